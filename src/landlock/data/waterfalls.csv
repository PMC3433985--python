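name,river,steps,height_m,age_printed_yr
Nakara Fall,Nakara R.,2,27.9,41858
Mariudo Fall,Urauchi R.,3,19.4,29106
Pinai Fall,Pinai R.,1,58.7,88067
Nishida Fall,Nishida R.,2,7.2,10802
Kura Fall,Kura R.,2,7.6,11402
Geta Fall,Geta R.,3,32.7,49060
Mayarock Fall,Yuchin R. (right stem),2,6.8,
Yuchin Right Fall,Yuchin R. (right stem),3,44.2,66313
Yuchin Left Fall,Yuchin R. (left stem),5,42.5,63763
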