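synonym,category_id
beef,beef
beef mince,beef
minced beef,beef
beef steak,beef
lamb,lamb
mutton,lamb
pork,pork
bacon,pork
ham,pork
chicken,chicken
chicken breast,chicken
turkey,turkey
egg,eggs
eggs,eggs
free range eggs,eggs
milk,milk
whole milk,milk
skimmed milk,milk
milk powder,milk
cheese,cheese
cheddar,cheese
cheddar cheese,cheese
mozzarella,cheese
parmesan,cheese
butter,butter
cream,cream
double cream,cream
yogurt,yogurt
yoghurt,yogurt
salmon,salmon
smoked salmon,salmon
cod,white_fish
haddock,white_fish
pollock,white_fish
tuna,white_fish
prawns,prawns
shrimp,prawns
wheat flour,wheat_flour
flour,wheat_flour
wholemeal flour,wheat_flour
semolina,wheat_flour
pasta,wheat_flour
breadcrumbs,wheat_flour
rice,rice
basmati rice,rice
oats,oats
rolled oats,oats
oatmeal,oats
maize,maize
corn,maize
cornflour,maize
sweetcorn,maize
barley,barley
malted barley,barley
sugar,sugar
cane sugar,sugar
glucose syrup,sugar
golden syrup,sugar
invert sugar syrup,sugar
dextrose,sugar
cocoa,cocoa
cocoa butter,cocoa
cocoa mass,cocoa
chocolate,cocoa
dark chocolate,cocoa
coffee,coffee
instant coffee,coffee
tea,tea
black tea,tea
rapeseed oil,rapeseed_oil
canola oil,rapeseed_oil
vegetable oil,rapeseed_oil
olive oil,olive_oil
extra virgin olive oil,olive_oil
sunflower oil,sunflower_oil
palm oil,palm_oil
potato,potatoes
potatoes,potatoes
tomato,tomatoes
tomatoes,tomatoes
tomato puree,tomatoes
tomato paste,tomatoes
onion,onions
onions,onions
red onion,onions
garlic,onions
carrot,carrots
carrots,carrots
peas,peas
garden peas,peas
beans,beans
kidney beans,beans
haricot beans,beans
chickpeas,beans
lentils,lentils
red lentils,lentils
soy,soy
soya,soy
tofu,soy
soya protein,soy
apple,apples
apples,apples
apple juice,apples
banana,bananas
bananas,bananas
orange,oranges
oranges,oranges
orange juice,oranges
strawberries,berries
raspberries,berries
blueberries,berries
grapes,grapes
raisins,grapes
sultanas,grapes
almonds,almonds
ground almonds,almonds
peanuts,peanuts
peanut butter,peanuts
basil,herbs
parsley,herbs
oregano,herbs
coriander,herbs
pepper,spices
black pepper,spices
paprika,spices
cinnamon,spices
salt,salt
sea salt,salt
water,water
spring water,water
carbonated water,water
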