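nutrient,sex,reference_type,value,unit,life_stage
choline,female,AI,400,mg,14-18 y
choline,male,AI,550,mg,14-18 y
potassium,female,AI,2300,mg,14-18 y
potassium,male,AI,3000,mg,14-18 y
calcium,female,RDA,1300,mg,14-18 y
calcium,male,RDA,1300,mg,14-18 y
folate,female,RDA,400,mcg DFE,14-18 y
folate,male,RDA,400,mcg DFE,14-18 y
magnesium,female,AI,360,mg,14-18 y
magnesium,male,AI,410,mg,14-18 y
zinc,female,RDA,9,mg,14-18 y
zinc,male,RDA,11,mg,14-18 y
vitamin_d,female,RDA,15,mcg,14-18 y
vitamin_d,male,RDA,15,mcg,14-18 y
vitamin_c,female,RDA,65,mg,14-18 y
vitamin_c,male,RDA,75,mg,14-18 y
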