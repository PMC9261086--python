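# Compact Spanish lemma lookup table: surface <TAB> lemma.
# Covers frequent inflected forms seen in spontaneous interview speech
# (common verb conjugations -> infinitive, frequent plurals -> singular).
# Unknown surfaces fall back to their lowercased form. The backend is
# pluggable; swap in a full morphological analyzer for production text.
es	ser
soy	ser
eres	ser
somos	ser
son	ser
era	ser
eran	ser
fue	ser
fui	ser
fuimos	ser
fueron	ser
sido	ser
siendo	ser
sea	ser
está	estar
estoy	estar
estás	estar
estamos	estar
están	estar
estaba	estar
estaban	estar
estuvo	estar
estado	estar
estando	estar
hay	haber
ha	haber
he	haber
has	haber
hemos	haber
han	haber
había	haber
habían	haber
hubo	haber
tengo	tener
tienes	tener
tiene	tener
tenemos	tener
tienen	tener
tenía	tener
tenían	tener
tuvo	tener
tuve	tener
tenido	tener
voy	ir
vas	ir
va	ir
vamos	ir
van	ir
iba	ir
iban	ir
fueras	ir
yendo	ir
ido	ir
hago	hacer
haces	hacer
hace	hacer
hacemos	hacer
hacen	hacer
hacía	hacer
hacían	hacer
hizo	hacer
hice	hacer
hecho	hacer
haciendo	hacer
digo	decir
dices	decir
dice	decir
decimos	decir
dicen	decir
decía	decir
decían	decir
dijo	decir
dije	decir
dicho	decir
diciendo	decir
quiero	querer
quieres	querer
quiere	querer
queremos	querer
quieren	querer
quería	querer
querían	querer
quiso	querer
puedo	poder
puedes	poder
puede	poder
podemos	poder
pueden	poder
podía	poder
podían	poder
pudo	poder
pude	poder
veo	ver
ves	ver
ve	ver
vemos	ver
ven	ver
veía	ver
vio	ver
visto	ver
viendo	ver
sé	saber
sabes	saber
sabe	saber
sabemos	saber
saben	saber
sabía	saber
supo	saber
vivo	vivir
vives	vivir
vive	vivir
vivimos	vivir
viven	vivir
vivía	vivir
trabajo	trabajar
trabajas	trabajar
trabaja	trabajar
trabajamos	trabajar
trabajan	trabajar
trabajaba	trabajar
pienso	pensar
piensas	pensar
piensa	pensar
pensamos	pensar
piensan	pensar
pensaba	pensar
siento	sentir
sientes	sentir
siente	sentir
sentimos	sentir
sienten	sentir
sentía	sentir
casas	casa
cosas	cosa
veces	vez
días	día
años	año
meses	mes
semanas	semana
horas	hora
personas	persona
gentes	gente
amigos	amigo
amigas	amiga
hermanos	hermano
hermanas	hermana
padres	padre
madres	madre
hijos	hijo
hijas	hija
niños	niño
niñas	niña
palabras	palabra
problemas	problema
trabajos	trabajo
estudios	estudio
médicos	médico
doctores	doctor
hospitales	hospital
pastillas	pastilla
remedios	remedio
voces	voz
ideas	idea
pensamientos	pensamiento
sentimientos	sentimiento
momentos	momento
lugares	lugar
ciudades	ciudad
países	país
familias	familia
colegios	colegio
escuelas	escuela
universidades	universidad
preguntas	pregunta
respuestas	respuesta
historias	historia
sueños	sueño
miedos	miedo
ganas	gana
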