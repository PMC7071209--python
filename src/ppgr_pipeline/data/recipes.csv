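dish_name,ingredient_name,mass_fraction
oatmeal with milk,oatmeal porridge,0.6
oatmeal with milk,whole milk,0.35
oatmeal with milk,butter,0.05
buckwheat with beef,buckwheat boiled,0.65
buckwheat with beef,beef boiled,0.3
buckwheat with beef,butter,0.05
fruit salad,apple,0.4
fruit salad,banana,0.3
fruit salad,orange,0.2
fruit salad,yogurt plain,0.1
cheese sandwich,white bread,0.6
cheese sandwich,hard cheese,0.3
cheese sandwich,butter,0.1
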