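menu,condition,choline_mg,potassium_mg,calcium_mg,folate_mcg,magnesium_mg,zinc_mg,vitamin_d_mcg,vitamin_c_mg
HUSS,as_given,386.6,4315.0,1428.7,432.7,425.8,12.5,10.3,164.8
HUSS,egg_substitution,496.7,4242.0,1436.0,443.7,420.7,12.3,11.3,162.6
DASH,as_given,369.0,4380.7,1444.7,534.9,530.1,12.9,8.3,152.5
DASH,egg_substitution,453.1,4325.1,1456.6,549.0,524.9,12.6,8.9,152.4
Harvard,as_given,425.1,3790.2,630.1,570.4,477.1,9.7,9.8,228.4
Harvard,egg_substitution,531.9,3715.8,630.4,572.6,465.8,9.7,9.5,224.0
HVEG,as_given,452.2,4436.2,1600.5,845.2,538.3,14.5,6.6,123.3
HVEG,egg_substitution,562.7,4308.6,1597.5,820.2,518.8,14.4,7.6,122.5
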