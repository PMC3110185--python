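chemical,endpoint,ac50_uM
Rotenone,cell_loss,0.20
Rotenone,diff_decrease,0.13
Nitrapyrin,cell_loss,0.081
Nitrapyrin,diff_decrease,0.18
Trifloxystrobin,cell_loss,0.72
Trifloxystrobin,diff_decrease,0.39
Fluoxastrobin,cell_loss,0.80
Fluoxastrobin,diff_decrease,0.99
Niclosamide,cell_loss,0.32
Niclosamide,diff_decrease,1.0
Propargite,cell_loss,1.5
Propargite,diff_decrease,1.2
Maleic hydrazide,cell_loss,0.39
Maleic hydrazide,diff_decrease,1.3
IPBC,cell_loss,2.2
IPBC,diff_decrease,1.4
Azoxystrobin,cell_loss,1.7
Azoxystrobin,diff_decrease,5.0
Etoxazole,cell_loss,14
Etoxazole,diff_decrease,6.6
Folpet,cell_loss,0.65
Folpet,diff_decrease,10
Fentin,cell_loss,1.3
Fentin,diff_decrease,12
Thidiazuron,cell_loss,12
Thidiazuron,diff_decrease,15
Difenoconazole,cell_loss,17
Difenoconazole,diff_decrease,18
Spiroxamine,diff_decrease,0.47
Diniconazole,diff_decrease,1.2
Triflumizole,diff_decrease,5.8
Methoxyfenozide,diff_decrease,6.3
Triadimenol,diff_decrease,8.2
Propiconazole,diff_decrease,9
Triclosan,diff_decrease,10
Endosulfan,diff_decrease,11
Imazalil,diff_decrease,11
Prochloraz,diff_decrease,12
Bifenazate,diff_decrease,15
Butafenacil,diff_decrease,16
Captafol,cell_loss,0.017
Acetamiprid,cell_loss,0.019
Thiram,cell_loss,0.11
Fluazinam,cell_loss,0.22
Cyromazine,cell_loss,1.3
Dicamba,cell_loss,1.4
Diquat dibromide,cell_loss,2.1
Imazamox,cell_loss,2.5
Naled,cell_loss,2.5
Phosalone,cell_loss,2.7
Milbemectin,cell_loss,2.9
Milbemectin,diff_increase,2.7
Benomyl,cell_loss,3.0
Abamectin,cell_loss,3.4
Mepiquat chloride,cell_loss,5.4
TCMTB,cell_loss,6
Fludioxonil,cell_loss,11
Maneb,cell_loss,12
Buprofezin,cell_loss,17
Dicrotophos,diff_increase,0.45
Diuron,diff_increase,9.7
Permethrin,diff_increase,15
Mancozeb,cell_gain,0.43
Captan,cell_gain,4.6
Cyazofamid,cell_gain,5.1
Bensulide,cell_gain,9.1
Oxadiazon,cell_gain,12
Dicofol,cell_gain,13
Profenofos,cell_gain,14
Fluroxypyr-meptyl,cell_gain,15
Sulfentrazone,cell_gain,17
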