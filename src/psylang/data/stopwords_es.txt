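# Base Spanish stop-word list (function words: articles, pronouns,
# determiners, prepositions, conjunctions, common adverbs and frequent
# auxiliary/copular verb forms). One entry per line, case-insensitive.
a
al
algo
alguien
alguna
algunas
alguno
algunos
algún
ahora
ahí
allá
allí
ambos
ante
antes
aquel
aquella
aquellas
aquello
aquellos
aqui
aquí
así
aun
aunque
bajo
bastante
bastantes
bien
cada
casi
cierta
ciertas
cierto
ciertos
como
con
conmigo
consigo
contigo
contra
cual
cuales
cualquier
cualquiera
cuando
cuanta
cuantas
cuanto
cuantos
cuya
cuyas
cuyo
cuyos
cuál
cuáles
cuándo
cuánta
cuántas
cuánto
cuántos
cómo
de
debe
deben
del
demasiada
demasiadas
demasiado
demasiados
demás
dentro
desde
después
donde
dos
durante
dónde
e
el
ella
ellas
ello
ellos
en
encima
entonces
entre
era
eran
eras
eres
es
esa
esas
ese
eso
esos
esta
estaba
estaban
estado
estamos
estar
estas
este
esto
estos
estoy
está
estábamos
están
estás
etc
fue
fuera
fueron
fui
fuimos
ha
haber
habia
habéis
había
habían
han
has
hasta
hay
haya
he
hemos
hube
hubo
igual
incluso
ir
iba
iban
jamás
la
las
le
les
lo
los
luego
mas
me
menos
mi
mientras
mis
misma
mismas
mismo
mismos
mucha
muchas
mucho
muchos
muy
más
mí
mía
mías
mío
míos
nada
nadie
ni
ninguna
ningunas
ninguno
ningunos
ningún
no
nos
nosotras
nosotros
nuestra
nuestras
nuestro
nuestros
nunca
o
os
otra
otras
otro
otros
para
pero
poca
pocas
poco
pocos
por
porque
pronto
pues
que
quien
quienes
quién
quiénes
qué
se
sea
sean
según
ser
si
sido
siempre
siendo
sin
sobre
sois
solamente
solo
somos
son
soy
su
sus
suya
suyas
suyo
suyos
sí
sólo
tal
tales
también
tampoco
tan
tanta
tantas
tanto
tantos
te
tendrá
tener
tenemos
tengo
tenía
tenían
ti
tiene
tienen
toda
todas
todavía
todo
todos
tras
tu
tus
tuya
tuyas
tuyo
tuyos
tú
u
un
una
unas
uno
unos
usted
ustedes
va
vamos
van
varias
varios
vaya
vosotras
vosotros
voy
vuestra
vuestras
vuestro
vuestros
y
ya
yo
él
ésa
ésas
ése
ésos
ésta
éstas
éste
éstos
tres
cuatro
cinco
seis
siete
ocho
nueve
diez
once
doce
veinte
treinta
cien
ciento
mil
primer
primera
primero
segunda
segundo
tercer
tercera
tercero
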