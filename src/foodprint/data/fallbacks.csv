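keyword,category_id
fruit,other_fruits
berry,other_fruits
berries,other_fruits
vegetable,other_vegetables
vegetables,other_vegetables
greens,other_vegetables
oil,other_oils
fat,other_oils
grain,other_grains
cereal,other_grains
bran,other_grains
nut,other_nuts
nuts,other_nuts
meat,other_meat
fish,white_fish
spice,spices
spices,spices
herb,herbs
herbs,herbs
cheese,cheese
milk,milk
syrup,sugar
juice,other_fruits
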