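# Dialectal stop-word extension: typical Chilean-Spanish colloquial
# expressions and discourse fillers that behave like stop words in
# spontaneous interview speech. This is a documented placeholder set —
# the mechanism (base list + user-editable extension) is the point;
# replace or extend it for a different dialect or corpus.
po
poh
pos
sipo
nopo
yapo
cachai
cachay
cacha
cacho
altiro
fome
bacán
bakán
filo
pucha
puchas
chuta
chutas
weon
weón
wea
weá
hueón
hueon
hueá
huea
cabro
cabra
cabros
cabras
pololo
polola
pololos
luca
lucas
gamba
gambas
caleta
harto
harta
hartos
hartas
cuático
cuática
penca
pencas
flaite
flaites
guagua
guaguas
fonda
copete
carrete
carretes
pololear
taco
tacos
micro
micros
pega
pegas
brígido
brígida
latero
latera
lata
latas
seco
seca
choro
chora
piola
pulento
pulenta
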