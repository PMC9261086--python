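# Spanish closed-class lexicon: word <TAB> class <TAB> subcategory.
# A word may carry one pronoun row and one determiner row; forms that are
# ambiguous between the two classes are disambiguated positionally at
# tagging time. The first row per (word, class) defines the subcategory.
yo	pronoun	personal
tú	pronoun	personal
vos	pronoun	personal
él	pronoun	personal
ella	pronoun	personal
ello	pronoun	personal
usted	pronoun	personal
nosotros	pronoun	personal
nosotras	pronoun	personal
vosotros	pronoun	personal
vosotras	pronoun	personal
ustedes	pronoun	personal
ellos	pronoun	personal
ellas	pronoun	personal
me	pronoun	personal
te	pronoun	personal
se	pronoun	personal
nos	pronoun	personal
os	pronoun	personal
le	pronoun	personal
les	pronoun	personal
mí	pronoun	personal
ti	pronoun	personal
sí	pronoun	personal
conmigo	pronoun	personal
contigo	pronoun	personal
consigo	pronoun	personal
lo	pronoun	personal
lo	determiner	definite_article
la	pronoun	personal
la	determiner	definite_article
los	pronoun	personal
los	determiner	definite_article
las	pronoun	personal
las	determiner	definite_article
el	determiner	definite_article
al	determiner	definite_article
del	determiner	definite_article
mío	pronoun	possessive
mía	pronoun	possessive
míos	pronoun	possessive
mías	pronoun	possessive
tuyo	pronoun	possessive
tuya	pronoun	possessive
tuyos	pronoun	possessive
tuyas	pronoun	possessive
suyo	pronoun	possessive
suya	pronoun	possessive
suyos	pronoun	possessive
suyas	pronoun	possessive
mi	determiner	possessive
mis	determiner	possessive
tu	determiner	possessive
tus	determiner	possessive
su	determiner	possessive
sus	determiner	possessive
nuestro	pronoun	possessive
nuestro	determiner	possessive
nuestra	pronoun	possessive
nuestra	determiner	possessive
nuestros	pronoun	possessive
nuestros	determiner	possessive
nuestras	pronoun	possessive
nuestras	determiner	possessive
vuestro	pronoun	possessive
vuestro	determiner	possessive
vuestra	pronoun	possessive
vuestra	determiner	possessive
vuestros	pronoun	possessive
vuestros	determiner	possessive
vuestras	pronoun	possessive
vuestras	determiner	possessive
esto	pronoun	demonstrative
eso	pronoun	demonstrative
aquello	pronoun	demonstrative
este	pronoun	demonstrative
este	determiner	demonstrative
esta	pronoun	demonstrative
esta	determiner	demonstrative
estos	pronoun	demonstrative
estos	determiner	demonstrative
estas	pronoun	demonstrative
estas	determiner	demonstrative
ese	pronoun	demonstrative
ese	determiner	demonstrative
esa	pronoun	demonstrative
esa	determiner	demonstrative
esos	pronoun	demonstrative
esos	determiner	demonstrative
esas	pronoun	demonstrative
esas	determiner	demonstrative
aquel	pronoun	demonstrative
aquel	determiner	demonstrative
aquella	pronoun	demonstrative
aquella	determiner	demonstrative
aquellos	pronoun	demonstrative
aquellos	determiner	demonstrative
aquellas	pronoun	demonstrative
aquellas	determiner	demonstrative
éste	pronoun	demonstrative
ésta	pronoun	demonstrative
éstos	pronoun	demonstrative
éstas	pronoun	demonstrative
ése	pronoun	demonstrative
ésa	pronoun	demonstrative
ésos	pronoun	demonstrative
ésas	pronoun	demonstrative
alguien	pronoun	indefinite
nadie	pronoun	indefinite
algo	pronoun	indefinite
nada	pronoun	indefinite
cualquiera	pronoun	indefinite
uno	pronoun	indefinite
uno	determiner	numeral
alguno	pronoun	indefinite
alguna	pronoun	indefinite
alguna	determiner	indefinite
algunos	pronoun	indefinite
algunos	determiner	indefinite
algunas	pronoun	indefinite
algunas	determiner	indefinite
ninguno	pronoun	indefinite
ninguna	pronoun	indefinite
ninguna	determiner	indefinite
varios	pronoun	indefinite
varios	determiner	indefinite
varias	pronoun	indefinite
varias	determiner	indefinite
muchos	pronoun	indefinite
muchos	determiner	indefinite
muchas	pronoun	indefinite
muchas	determiner	indefinite
mucho	pronoun	indefinite
mucho	determiner	indefinite
mucha	determiner	indefinite
pocos	pronoun	indefinite
pocos	determiner	indefinite
pocas	pronoun	indefinite
pocas	determiner	indefinite
poco	pronoun	indefinite
poco	determiner	indefinite
poca	determiner	indefinite
todo	pronoun	indefinite
todo	determiner	indefinite
toda	determiner	indefinite
todos	pronoun	indefinite
todos	determiner	indefinite
todas	pronoun	indefinite
todas	determiner	indefinite
otro	pronoun	indefinite
otro	determiner	indefinite
otra	pronoun	indefinite
otra	determiner	indefinite
otros	pronoun	indefinite
otros	determiner	indefinite
otras	pronoun	indefinite
otras	determiner	indefinite
demás	pronoun	indefinite
bastante	pronoun	indefinite
bastante	determiner	indefinite
bastantes	pronoun	indefinite
bastantes	determiner	indefinite
algún	determiner	indefinite
ningún	determiner	indefinite
cualquier	determiner	indefinite
cierto	determiner	indefinite
cierta	determiner	indefinite
ciertos	determiner	indefinite
ciertas	determiner	indefinite
un	determiner	indefinite
una	determiner	indefinite
unos	determiner	indefinite
unas	determiner	indefinite
qué	pronoun	interrogative
qué	determiner	interrogative
quién	pronoun	interrogative
quiénes	pronoun	interrogative
cuál	pronoun	interrogative
cuál	determiner	interrogative
cuáles	pronoun	interrogative
cuáles	determiner	interrogative
cuánto	pronoun	interrogative
cuánto	determiner	interrogative
cuánta	pronoun	interrogative
cuánta	determiner	interrogative
cuántos	pronoun	interrogative
cuántos	determiner	interrogative
cuántas	pronoun	interrogative
cuántas	determiner	interrogative
que	pronoun	relative
quien	pronoun	relative
quienes	pronoun	relative
cual	pronoun	relative
cuales	pronoun	relative
cuanto	pronoun	relative
cuanta	pronoun	relative
cuantos	pronoun	relative
cuantas	pronoun	relative
cuyo	determiner	relative
cuya	determiner	relative
cuyos	determiner	relative
cuyas	determiner	relative
dos	determiner	numeral
tres	determiner	numeral
cuatro	determiner	numeral
cinco	determiner	numeral
seis	determiner	numeral
siete	determiner	numeral
ocho	determiner	numeral
nueve	determiner	numeral
diez	determiner	numeral
once	determiner	numeral
doce	determiner	numeral
veinte	determiner	numeral
treinta	determiner	numeral
cien	determiner	numeral
ciento	determiner	numeral
mil	determiner	numeral
ambos	determiner	numeral
ambas	determiner	numeral
primer	determiner	numeral
primera	determiner	numeral
primero	determiner	numeral
segundo	determiner	numeral
segunda	determiner	numeral
tercer	determiner	numeral
tercera	determiner	numeral
tercero	determiner	numeral
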