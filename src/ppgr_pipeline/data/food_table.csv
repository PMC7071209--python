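name,carb_per100,prot_per100,fat_per100,kcal_per100,water_per100,starch_per100,fiber_per100,gi,gi_rule
beef boiled,0.0,25.8,16.8,254,60.0,0.0,0.0,0,zero_carb
chicken breast,0.4,29.8,1.8,137,69.0,0.0,0.0,0,zero_carb
pork stew,0.0,24.0,22.0,300,55.0,0.0,0.0,0,zero_carb
turkey fillet,0.2,28.0,4.0,150,67.0,0.0,0.0,0,zero_carb
salmon baked,0.0,22.0,12.0,200,64.0,0.0,0.0,0,zero_carb
cod poached,0.0,20.0,0.9,90,78.0,0.0,0.0,0,zero_carb
herring salted,1.5,17.5,11.4,180,62.0,0.0,0.0,0,zero_carb
egg boiled,0.7,12.8,11.6,157,74.0,0.0,0.0,0,zero_carb
butter,0.8,0.5,82.5,748,16.0,0.0,0.0,0,zero_carb
sunflower oil,0.0,0.0,99.9,899,0.1,0.0,0.0,0,zero_carb
hard cheese,2.0,26.0,27.4,364,41.0,0.0,0.0,0,zero_carb
cottage cheese 5%,3.0,17.2,5.0,121,75.0,0.0,0.0,30,published
sour cream 15%,3.6,2.6,15.0,158,77.5,0.0,0.0,0,zero_carb
mushrooms fried,3.9,3.7,4.5,68,84.0,0.0,1.2,0,zero_carb
cucumber fresh,2.8,0.8,0.1,15,95.0,0.0,1.0,0,zero_carb
tomato fresh,3.8,1.1,0.2,20,93.5,0.3,1.4,15,published
cabbage stewed,5.2,2.0,3.3,50,90.0,0.1,2.0,15,close_match
carrot boiled,5.0,0.8,0.3,25,91.0,0.2,2.4,39,published
beetroot boiled,8.8,1.8,0.0,49,86.0,0.2,2.8,64,published
green peas,13.8,5.0,0.2,73,80.0,6.8,5.5,48,published
whole milk,4.7,3.2,3.6,64,87.3,0.0,0.0,31,published
kefir 2.5%,4.0,3.0,2.5,53,89.0,0.0,0.0,32,close_match
yogurt plain,6.2,4.3,2.0,60,86.0,0.0,0.0,36,published
apple,9.8,0.4,0.4,47,86.3,0.8,1.8,36,published
pear,10.3,0.4,0.3,47,85.0,0.5,2.8,38,published
orange,8.1,0.9,0.2,43,86.8,0.0,2.2,43,published
peach,9.5,0.9,0.1,45,86.1,0.0,2.1,42,close_match
apricot,9.0,0.9,0.1,44,86.2,0.0,2.1,57,close_match
banana,21.0,1.5,0.2,96,74.0,2.0,1.7,51,published
grapes,15.4,0.6,0.2,65,80.5,0.0,1.6,59,published
strawberry,7.5,0.8,0.4,41,87.4,0.1,2.2,40,subgroup_mean
dried apricots,51.0,5.2,0.3,215,20.0,0.0,11.0,32,published
white bread,48.8,7.6,0.8,242,37.7,46.0,2.7,75,subgroup_mean
rye bread,39.8,6.6,1.2,200,42.0,37.0,5.8,58,subgroup_mean
whole grain bread,41.0,8.0,1.4,213,40.0,38.0,7.0,53,subgroup_mean
buckwheat boiled,17.1,4.2,1.1,92,72.0,16.0,2.7,54,published
rice white boiled,24.9,2.2,0.5,116,68.6,24.0,0.4,73,published
oatmeal porridge,11.5,2.4,1.4,68,84.0,10.5,1.3,55,published
pasta boiled,23.2,3.6,0.4,112,70.0,22.5,1.8,49,published
potato boiled,16.3,2.0,0.4,82,77.0,15.5,1.8,78,published
potato mashed,14.5,1.9,3.3,106,76.0,13.8,1.5,87,published
pearl barley boiled,22.2,3.1,0.4,109,70.0,21.5,3.8,28,published
lentils boiled,16.9,7.8,0.4,105,70.0,15.0,7.9,32,published
white beans boiled,20.5,7.8,0.5,123,67.0,17.0,6.3,24,published
sugar,99.8,0.0,0.0,399,0.1,0.0,0.0,65,published
honey,80.3,0.8,0.0,329,17.4,0.0,0.2,61,published
milk chocolate,54.4,6.9,35.7,554,0.8,2.9,2.0,43,published
oat cookies,71.0,6.5,14.4,437,6.5,35.0,2.2,77,published
apple jam,68.2,0.4,0.0,265,30.0,0.0,1.0,65,expert_default
fruit juice,11.2,0.5,0.1,46,87.8,0.0,0.1,50,expert_default
buckwheat flakes,71.9,12.6,3.3,366,10.0,65.0,10.0,54,close_match
fern salad,6.5,4.6,0.2,34,88.0,0.0,3.0,,
jerusalem artichoke stew,12.8,2.1,0.1,61,79.0,9.6,4.5,,
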