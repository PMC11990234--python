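menu,condition,day,price_usd
HUSS,as_given,1,7.6
HUSS,as_given,2,7.7
HUSS,as_given,3,9.9
HUSS,as_given,4,10.6
HUSS,as_given,5,10.3
HUSS,as_given,6,10.2
HUSS,as_given,7,11.0
HUSS,egg_substitution,1,7.4
HUSS,egg_substitution,2,7.7
HUSS,egg_substitution,3,9.8
HUSS,egg_substitution,4,10.6
HUSS,egg_substitution,5,10.1
HUSS,egg_substitution,6,10.2
HUSS,egg_substitution,7,10.8
Harvard,as_given,1,6.0
Harvard,as_given,2,6.3
Harvard,as_given,3,5.4
Harvard,as_given,4,5.5
Harvard,as_given,5,7.9
Harvard,as_given,6,8.4
Harvard,as_given,7,5.1
Harvard,egg_substitution,1,5.9
Harvard,egg_substitution,2,5.8
Harvard,egg_substitution,3,5.4
Harvard,egg_substitution,4,5.2
Harvard,egg_substitution,5,7.8
Harvard,egg_substitution,6,8.3
Harvard,egg_substitution,7,5.0
DASH,as_given,1,5.7
DASH,as_given,2,5.1
DASH,as_given,3,6.7
DASH,as_given,4,7.0
DASH,as_given,5,5.5
DASH,as_given,6,6.4
DASH,as_given,7,6.1
DASH,egg_substitution,1,5.6
DASH,egg_substitution,2,5.0
DASH,egg_substitution,3,6.1
DASH,egg_substitution,4,6.8
DASH,egg_substitution,5,5.5
DASH,egg_substitution,6,6.4
DASH,egg_substitution,7,5.9
HVEG,as_given,1,8.0
HVEG,as_given,2,5.1
HVEG,as_given,3,6.5
HVEG,as_given,4,10.7
HVEG,as_given,5,5.5
HVEG,as_given,6,5.0
HVEG,as_given,7,6.7
HVEG,egg_substitution,1,7.7
HVEG,egg_substitution,2,5.1
HVEG,egg_substitution,3,6.6
HVEG,egg_substitution,4,10.6
HVEG,egg_substitution,5,5.5
HVEG,egg_substitution,6,5.1
HVEG,egg_substitution,7,6.8
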