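endpoint,ddref,a,b,c,d
incidence,1,-0.0000262499999999986,0.00628928571428544,-0.512089285714269,14.2150714285711
incidence,1.5,-0.0000174999999999991,0.00419285714285698,-0.341392857142847,9.47671428571409
incidence,2,-0.0000131249999999993,0.00314464285714272,-0.256044642857134,7.10753571428554
mortality,1,-0.00000624999999999958,0.00146785714285707,-0.118517857142853,3.31821428571419
mortality,1.5,-0.00000416666666666648,0.000978571428571391,-0.0790119047619024,2.21214285714281
mortality,2,-0.00000312499999999979,0.000733928571428534,-0.0592589285714263,1.6591071428571
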