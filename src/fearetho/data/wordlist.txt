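abundant
acorn
actor
adrift
afloat
agile
almond
amber
ancient
anchor
antique
apple
arbor
ardent
aspen
atlas
auburn
autumn
avid
awake
badge
bamboo
banner
barley
basil
beacon
bedrock
berry
birch
bison
blazing
bold
bonfire
boulder
bramble
brave
breeze
bright
bronze
brook
bustling
cabin
calm
canyon
carbon
cedar
cherry
chestnut
cinder
citrus
clever
cliff
clover
coast
cobalt
comet
copper
coral
cosmic
cotton
cove
crimson
crisp
crystal
curious
cypress
daring
dawn
delta
dew
drift
dune
dusk
eager
early
ebony
echo
elder
elm
ember
emerald
evening
fable
falcon
fern
fierce
flint
forest
fortune
fossil
fox
frost
garnet
gentle
ginger
glacier
glade
gleam
golden
granite
grove
hazel
heather
hidden
hollow
honest
humble
indigo
iris
iron
island
ivory
jade
jasper
jolly
juniper
keen
kindred
lagoon
lantern
larch
laurel
lavender
lichen
lilac
linden
lively
lotus
lucid
lunar
magnet
mango
maple
marble
meadow
mellow
merry
mesa
mint
mirror
misty
modest
morning
mossy
mountain
nectar
nimble
noble
north
nutmeg
oak
ocean
olive
onyx
opal
orchard
osprey
otter
pebble
pepper
pine
placid
plain
plum
polar
poplar
prairie
prism
quartz
quiet
radiant
rain
rapid
raven
reed
ridge
river
robin
rustic
saffron
sage
sandy
sapphire
scarlet
serene
shadow
silent
silver
sincere
slate
solar
spruce
steady
stone
storm
summit
sunny
swift
tawny
thistle
thunder
timber
topaz
tranquil
tulip
tundra
twilight
umber
valley
velvet
verdant
violet
vivid
walnut
wander
willow
winter
wise
wren
zephyr
zesty
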