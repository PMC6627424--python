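category_id,display_name,group,children_t1_g,adults_t1_g
coffee_tea,Coffee & Tea,Beverages,24.3,231.4
diet_beverages,Diet Beverages,Beverages,2.6,12.4
sweetened_beverages,Sweetened Beverages,Beverages,55.9,75.5
fats_oils,Fats & Oils,Fats & Oils,1.7,9.1
fruit,Fruit,Fruit,8.9,9.3
juice_100,100% Juice,Fruit,19.5,15.8
breads,Breads,Grains,7.3,16.2
cooked_grains,Cooked grains,Grains,6.9,8.4
grains,Grains,Grains,0.9,1.3
quick_breads,Quick Breads,Grains,20.0,11.6
rte_cereal_high_sugar,High Sugar RTE Cereal,Grains,6.4,3.3
rte_cereal_low_sugar,Low Sugar RTE Cereal,Grains,0.8,1.7
cheese,Cheese,Milk & Dairy,0.8,2.2
flavored_milk,Flavored Milk,Milk & Dairy,9.7,4.5
milk,Milk,Milk & Dairy,75.1,32.8
milk_dessert_drinks,Milk Dessert Drinks,Milk & Dairy,0.8,0.6
yogurt,Yogurt,Milk & Dairy,2.7,4.5
mixed_dishes,Mixed Dishes,Mixed Dishes,26.8,33.7
eggs,Eggs,Protein Foods,12.9,21.7
nuts_beans_soy,"Nuts, Beans & Soy",Protein Foods,0.5,1.8
processed_meat,Processed Meat,Protein Foods,6.4,9.1
seafood_meat,Seafood/Meat,Protein Foods,2.2,4.9
candy,Candy,Snacks & Sweets,0.6,0.3
crackers,Crackers,Snacks & Sweets,0.5,0.4
other_desserts,Other Desserts,Snacks & Sweets,0.3,1.0
savory_snacks,Savory Snacks,Snacks & Sweets,0.9,0.7
snack_meal_bars,Snack/Meal Bars,Snacks & Sweets,0.4,1.0
sweet_bakery,Sweet Bakery,Snacks & Sweets,20.6,12.8
sugars,Sugars,Sugars,7.5,8.6
vegetables_nonpotato,"Vegetables, Non-potato",Vegetables,0.4,2.2
white_potatoes,White Potatoes,Vegetables,1.7,8.7
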