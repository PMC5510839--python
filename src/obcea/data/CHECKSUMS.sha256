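5d87d54eefa9fd641582931be6516e5f62819a4dcccbf71563ecdd25d666d16f  hospital_years.csv
482c4056e2481bddcff7cefbee170daf5c3b226ba976b1b043bfec9fb1fda50a  budget.csv
7b504171475cbaeecdddb89e585cffdc4803aa429ef1baedf680588688b9b354  life_table_synthetic.csv
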