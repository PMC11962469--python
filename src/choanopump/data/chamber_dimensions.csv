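species,chamber_diameter_um,chamber_diameter_sd_um,apopyle_diameter_um,apopyle_diameter_sd_um,apopyle_area_um2,theta_a_deg,theta_a_sd_deg,choanocytes_per_chamber,choanocytes_sd
Ephydatia muelleri,34.7,5.0,18.1,4.3,,32.2,6.7,112,31
Haliclona urceolus,30,,14,,,27.8,,80,
Haliclona permollis,30,,14,,,27.8,,95,
Aphrocallistes vastus,56,,26,,,27.7,,260,
Neopetrosia problematica,23.3,,16.0,,,43.4,,80,
Haliclona mollis,28.5,,14.1,,,29.7,,139,
Tethya californiana,21.1,,0.90,,,2.44,,99,
Callyspongia vaginalis,19.7,,5.97,,,17.6,,93,
Cliona delitrix,16.0,,4.23,,,15.3,,50,
Amorphinopsis foetida,17.46,0.13,,,124.11,46.1,,84.11,3.02
Callyspongia sp.,19.35,0.2,,,168.54,49.2,,121.11,4.33
Haliclona sp.,19.69,0.23,,,113.21,37.6,,68.83,2.82
Ircinia fusca,30.68,0.29,,,211.25,32.3,,120.35,8.98
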