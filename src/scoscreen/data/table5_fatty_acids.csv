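strain,medium,C12:0,C14:0,C16:0,C16:1,C17:1,C18:0,C18:1,C18:2,C18:3 n-3,C20:1 n-9,C20:3 n-6,C20:4 n-6,C22:2,C22:4,C24:0
Candida inconspicua IG 11,YPGlc,n.d.,n.d.,16.61,2.18,n.d.,12.28,48.5,18.28,2.15,n.d.,n.d.,n.d.,n.d.,n.d.,n.d.
Debaryomyces hansenii 1,YPGlc,n.d.,n.d.,15.94,3.80,n.d.,11.50,46.20,15.21,2.53,0.89,n.d.,n.d.,n.d.,3.93,n.d.
Debaryomyces hansenii IG II,YPGlc,0.33,n.d.,17.85,3.79,n.d.,12.03,37.69,14.18,1.42,0.92,n.d.,n.d.,n.d.,4.97,6.82
Debaryomyces hansenii IG 01,YPGlc,n.d.,n.d.,14.04,1.80,n.d.,11.23,60.25,8.68,n.d.,0.92,n.d.,n.d.,n.d.,n.d.,3.08
Kazachstania unispora IG 16,YPGlc,n.d.,2.37,8.31,39.61,n.d.,2.09,20.83,n.d.,1.92,n.d.,5.47,8.14,2.09,n.d.,9.17
Kluyveromyces marxianus IG 1,YPGlc,n.d.,n.d.,14.95,10.61,n.d.,5.21,34.87,10.66,1.78,2.54,n.d.,6.28,n.d.,n.d.,13.1
Zygotorulaspora florentina IG 12,YPGlc,n.d.,0.65,17.21,9.61,0.49,8.28,43.39,10.48,0.54,n.d.,n.d.,2.11,3.18,n.d.,4.06
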