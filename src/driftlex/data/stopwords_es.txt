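de
la
que
el
en
los
se
del
las
por
un
para
con
no
una
su
al
lo
como
mas
pero
sus
le
ya
o
este
si
porque
esta
entre
cuando
muy
sin
sobre
tambien
me
hasta
hay
donde
quien
desde
todo
nos
durante
todos
uno
les
ni
contra
otros
ese
eso
ante
ellos
e
esto
mi
antes
algunos
que
unos
yo
otro
otras
otra
el
tanto
esa
estos
mucho
quienes
nada
muchos
cual
poco
ella
estar
estas
algunas
algo
nosotros
mis
tu
te
ti
tus
ellas
nosotras
vosotros
vosotras
os
mio
mia
mios
mias
tuyo
tuya
tuyos
tuyas
suyo
suya
suyos
suyas
nuestro
nuestra
nuestros
nuestras
vuestro
vuestra
vuestros
vuestras
esos
esas
estoy
estas
esta
estamos
estais
estan
ser
es
soy
eres
somos
sois
son
era
fue
ha
han
he
has
hemos
habeis
haber
tengo
tiene
tienen
tener
hacer
hace
hacen
va
van
vamos
ir
aqui
ahi
alli
asi
bien
solo
ahora
despues
luego
pues
cada
vez
ver
dia
dos
tres
ello
debe
puede
pueden
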