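strain,medium_family,duration_h,biomass_glc,biomass_sd_glc,biomass_lac,biomass_sd_lac,biomass_gly,biomass_sd_gly,lipids_glc,lipids_sd_glc,lipids_lac,lipids_sd_lac,lipids_gly,lipids_sd_gly,ph_glc,ph_lac,ph_gly
Candida inconspicua IG 11,YP,96,12.2,0.02,13.5,0.3,9.8,0.02,4.04,0.12,3.38,0.11,1.71,0.22,5.10,5.17,5.62
Debaryomyces hansenii 1,YP,96,13.5,0.03,12.9,0.2,11.8,0.03,6.31,0.23,2.02,0.09,2.26,0.21,7.31,7.58,6.01
Debaryomyces hansenii IG II,YP,96,13.8,0.01,13.0,0.5,13.6,0.04,1.14,0.03,1.77,0.07,3.28,0.31,6.69,6.97,7.46
Debaryomyces hansenii IG 01,YP,96,14.8,0.02,10.7,0.2,10.2,0.01,5.65,0.15,1.78,0.08,1.85,0.14,7.23,7.69,7.63
Kazachstania unispora IG 16,YP,96,11.0,0.01,10.4,0.4,12.1,0.50,1.70,0.05,1.32,0.09,0.87,0.09,4.29,5.19,6.30
Kluyveromyces marxianus IG 1,YP,96,12.9,0.05,12.2,0.5,10.7,0.50,3.71,0.06,4.76,0.18,0.50,0.09,7.31,7.09,7.03
Zygotorulaspora florentina IG 12,YP,96,13.7,0.04,12.4,0.1,11.3,0.03,4.44,0.07,1.97,0.12,2.34,0.19,5.79,6.31,5.04
Candida inconspicua IG 11,DPW,96,10.5,0.01,10.9,0.21,10.9,0.02,0.36,0.07,1.58,0.15,2.35,0.11,8.51,8.00,8.01
Debaryomyces hansenii 1,DPW,96,12.3,0.11,11.6,0.15,11.0,0.03,1.12,0.06,1.99,0.09,1.79,0.09,7.56,7.93,8.44
Debaryomyces hansenii IG II,DPW,96,11.7,0.02,12.4,0.02,10.8,0.06,0.85,0.11,0.69,0.02,1.92,0.51,7.30,8.43,8.63
Debaryomyces hansenii IG 01,DPW,96,11.4,0.05,11.7,0.05,10.5,0.05,2.80,0.12,2.43,0.16,2.21,0.21,7.10,8.09,8.57
Kazachstania unispora IG 16,DPW,96,9.9,0.05,11.6,0.11,10.3,0.11,0.79,0.09,1.91,0.11,2.22,0.16,8.13,8.00,8.01
Kluyveromyces marxianus IG 1,DPW,96,10.3,0.02,11.4,0.02,10.7,0.08,3.56,0.12,1.74,0.09,2.16,0.22,7.94,8.52,8.42
Zygotorulaspora florentina IG 12,DPW,96,10.1,0.03,11.9,0.50,11.1,0.08,0.52,0.21,0.85,0.07,1.97,0.19,7.13,8.13,8.28
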