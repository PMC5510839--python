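year,deliveries,maternal_deaths_total,deaths_OH,deaths_HDoP,deaths_other,cases_OH,cases_HDoP,stillbirths_intrapartum
2007,6049,30,8,10,12,54,321,55
2008,7465,29,5,8,16,97,582,40
2009,8230,27,6,11,10,321,996,48
2010,8133,30,7,11,12,342,1033,45
2011,9357,36,8,15,13,487,1357,40
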