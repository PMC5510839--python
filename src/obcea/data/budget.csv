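label,funder,amount
Jan-07,organization,4120
Jan-07,participant,29310
Jan-07,host_government,8240
Jan-07,time_value,135910
Mar-07,organization,0
Mar-07,participant,2290
Mar-07,host_government,0
Mar-07,time_value,6300
Jun-07,organization,340
Jun-07,participant,18430
Jun-07,host_government,2180
Jun-07,time_value,28970
Jan-08,organization,880
Jan-08,participant,21710
Jan-08,host_government,7930
Jan-08,time_value,103150
Mar-08,organization,3530
Mar-08,participant,8380
Mar-08,host_government,1210
Mar-08,time_value,7270
May-08,organization,330
May-08,participant,7270
May-08,host_government,2200
May-08,time_value,11680
Sep-08,organization,6940
Sep-08,participant,16750
Sep-08,host_government,1980
Sep-08,time_value,53120
Jan-09,organization,3100
Jan-09,participant,22890
Jan-09,host_government,2770
Jan-09,time_value,97770
May-09,organization,770
May-09,participant,14600
May-09,host_government,1660
May-09,time_value,36500
Sep-09,organization,6300
Sep-09,participant,28420
Sep-09,host_government,4090
Sep-09,time_value,67240
Jan-10,organization,4460
Jan-10,participant,34920
Jan-10,host_government,8700
Jan-10,time_value,138390
May-10,organization,3370
May-10,participant,27090
May-10,host_government,2830
May-10,time_value,75720
Sep-10,organization,4130
Sep-10,participant,19800
Sep-10,host_government,4460
Sep-10,time_value,79420
Jan-11,organization,2430
Jan-11,participant,29750
Jan-11,host_government,6960
Jan-11,time_value,153710
May-11,organization,9810
May-11,participant,26060
May-11,host_government,6120
May-11,time_value,65300
Aug-11,organization,3060
Aug-11,participant,0
Aug-11,host_government,0
Aug-11,time_value,5800
Sep-11,organization,9920
Sep-11,participant,31230
Sep-11,host_government,9500
Sep-11,time_value,143160
US/UK Visits,organization,13740
US/UK Visits,participant,1650
US/UK Visits,host_government,0
US/UK Visits,time_value,0
Conference/Meals,organization,0
Conference/Meals,participant,0
Conference/Meals,host_government,91670
Conference/Meals,time_value,0
Capital,organization,452320
Capital,participant,0
Capital,host_government,120900
Capital,time_value,0
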