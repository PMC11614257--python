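region,expected,identified,notified,reviewed,reviewed_community,reviewed_facility
Addis Ababa,2268,414,340,274,49,225
Afar,1273,188,87,78,41,37
Amhara,10552,1707,1456,1250,836,414
Benishangul-Gumuz,857,157,118,78,41,37
Dire Dawa,371,177,121,165,29,136
Gambella,381,81,43,32,19,13
Harari,190,155,123,87,8,79
Oromia,25183,3087,2564,1409,776,633
SNNPR,12648,685,443,562,173,389
Somali,4201,221,136,29,8,21
Tigray,2715,598,265,566,444,122
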