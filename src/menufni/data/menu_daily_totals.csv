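menu,condition,day,choline_mg,potassium_mg,calcium_mg,folate_mcg,magnesium_mg,zinc_mg,vitamin_d_mcg,vitamin_c_mg
HUSS,as_given,1,512.8,3485.1,1339.0,368.6,340.2,11.9,32.3,189.4
HUSS,as_given,2,255.9,3875.7,1445.0,543.3,471.4,11.6,4.6,139.8
HUSS,as_given,3,338.0,5003.1,1336.4,454.8,446.8,10.8,9.3,87.0
HUSS,as_given,4,434.5,4141.1,1480.2,596.7,396.6,11.2,6.9,166.8
HUSS,as_given,5,409.5,4317.4,1272.8,245.7,384.8,18.4,6.1,201.4
HUSS,as_given,6,361.6,4582.3,1599.9,414.3,366.7,11.2,7.4,136.8
HUSS,as_given,7,393.7,4800.3,1527.8,405.5,574.2,12.0,6.1,232.4
HUSS,egg_substitution,1,614.3,3447.8,1355.0,385.8,338.3,11.1,33.1,189.4
HUSS,egg_substitution,2,364.9,3858.2,1454.0,560.8,468.4,11.1,5.5,139.8
HUSS,egg_substitution,3,434.1,4961.1,1352.5,472.6,440.6,10.8,10.2,87.0
HUSS,egg_substitution,4,558.2,4099.3,1494.9,591.0,391.5,11.4,7.9,164.6
HUSS,egg_substitution,5,519.3,4315.7,1288.5,263.4,383.8,18.3,7.0,201.4
HUSS,egg_substitution,6,483.1,4411.8,1587.0,417.0,357.6,11.3,8.3,131.9
HUSS,egg_substitution,7,503.4,4600.3,1519.8,415.1,564.4,12.2,7.0,224.2
DASH,as_given,1,408.9,4543.3,1322.1,397.3,559.4,15.3,9.1,143.0
DASH,as_given,2,311.3,4214.1,1483.5,510.2,534.4,11.4,5.7,98.1
DASH,as_given,3,383.9,4670.1,1533.2,837.7,636.3,14.2,8.6,211.8
DASH,as_given,4,404.3,4376.3,1474.7,343.1,457.4,12.6,8.9,112.3
DASH,as_given,5,377.7,4078.1,1409.5,521.2,469.5,13.5,7.4,174.3
DASH,as_given,6,414.3,4319.2,1399.8,531.5,504.4,10.1,8.3,252.9
DASH,as_given,7,282.7,4464.1,1489.7,603.0,549.3,14.0,10.2,75.4
DASH,egg_substitution,1,512.9,4514.0,1338.0,413.8,555.5,15.1,10.0,142.8
DASH,egg_substitution,2,407.4,4172.1,1499.6,528.0,528.1,11.3,6.6,98.1
DASH,egg_substitution,3,479.2,4561.8,1548.4,854.9,634.3,12.7,9.6,211.8
DASH,egg_substitution,4,493.6,4296.7,1493.0,361.1,455.2,11.8,9.5,112.3
DASH,egg_substitution,5,475.8,4034.4,1419.3,534.5,461.5,13.0,8.2,173.7
DASH,egg_substitution,6,414.3,4319.2,1399.8,531.5,504.4,10.1,8.3,252.9
DASH,egg_substitution,7,388.7,4377.6,1498.3,619.2,535.5,13.9,10.2,75.4
Harvard,as_given,1,425.4,4698.0,674.9,620.1,435.9,10.2,2.0,277.3
Harvard,as_given,2,297.3,3053.4,707.2,656.7,487.9,9.5,36.2,205.5
Harvard,as_given,3,388.7,3716.4,535.6,576.9,426.4,9.6,1.1,91.4
Harvard,as_given,4,382.8,3798.5,765.1,528.3,431.1,8.4,2.2,353.0
Harvard,as_given,5,364.7,3151.3,478.0,562.2,487.7,8.0,17.1,232.1
Harvard,as_given,6,511.7,4134.1,671.8,471.1,538.5,11.8,7.5,218.3
Harvard,as_given,7,604.9,3979.7,578.4,577.6,532.1,10.2,2.4,221.3
Harvard,egg_substitution,1,521.5,4656.1,691.0,637.9,429.6,10.2,2.9,277.3
Harvard,egg_substitution,2,385.6,2915.9,721.0,665.6,477.5,9.8,28.4,196.0
Harvard,egg_substitution,3,503.5,3708.1,534.9,581.6,423.3,9.8,2.0,90.6
Harvard,egg_substitution,4,480.7,3742.1,751.1,521.5,413.1,8.2,3.0,351.1
Harvard,egg_substitution,5,477.0,2962.6,464.1,536.9,468.4,8.0,18.1,220.4
Harvard,egg_substitution,6,629.7,4088.3,665.8,483.2,527.7,11.6,8.5,215.3
Harvard,egg_substitution,7,725.6,3937.5,585.2,581.9,520.9,10.4,3.3,217.8
HVEG,as_given,1,606.3,4326.9,1739.7,988.6,549.1,15.8,7.3,123.2
HVEG,as_given,2,350.0,4055.3,1688.0,730.2,596.0,13.1,7.4,79.1
HVEG,as_given,3,539.3,4686.2,1450.2,900.1,409.1,13.0,6.4,79.3
HVEG,as_given,4,372.2,4710.6,1367.0,990.1,629.9,19.8,6.8,197.2
HVEG,as_given,5,574.2,4183.1,1733.0,672.4,521.9,13.7,6.6,153.6
HVEG,as_given,6,380.1,4297.0,1993.9,757.7,591.5,13.2,7.4,147.7
HVEG,as_given,7,343.6,4794.6,1231.7,877.1,470.5,12.7,4.4,83.2
HVEG,egg_substitution,1,703.7,4168.9,1726.5,957.4,523.8,15.6,8.3,123.2
HVEG,egg_substitution,2,462.0,3835.5,1665.8,709.8,569.5,12.9,8.3,79.1
HVEG,egg_substitution,3,649.4,4524.6,1461.0,813.0,392.3,12.7,7.3,78.4
HVEG,egg_substitution,4,485.4,4524.3,1367.0,1001.1,607.8,19.8,7.7,192.7
HVEG,egg_substitution,5,697.1,4155.9,1748.1,678.1,506.2,13.8,7.6,153.6
HVEG,egg_substitution,6,491.8,4290.7,1993.8,753.5,583.1,13.4,8.4,147.7
HVEG,egg_substitution,7,451.1,4660.5,1220.1,828.2,449.1,12.7,5.4,82.8
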