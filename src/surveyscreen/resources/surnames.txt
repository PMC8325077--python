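# Common US surnames, roughly frequency-ranked
smith
johnson
williams
brown
jones
garcia
miller
davis
rodriguez
martinez
hernandez
lopez
gonzalez
wilson
anderson
thompson
taylor
moore
jackson
martin
lee
perez
white
harris
sanchez
clark
ramirez
lewis
robinson
walker
young
allen
king
wright
torres
nguyen
hill
flores
green
adams
nelson
baker
hall
rivera
campbell
mitchell
carter
roberts
gomez
phillips
evans
turner
diaz
parker
cruz
edwards
collins
reyes
stewart
morris
morales
murphy
cook
rogers
gutierrez
ortiz
morgan
cooper
peterson
bailey
reed
kelly
howard
ramos
kim
cox
ward
richardson
watson
brooks
chavez
wood
james
bennett
gray
mendoza
ruiz
hughes
price
alvarez
castillo
sanders
patel
myers
long
ross
foster
jimenez
powell
jenkins
perry
russell
sullivan
bell
coleman
butler
henderson
barnes
fisher
vasquez
simmons
romero
jordan
patterson
alexander
hamilton
graham
reynolds
griffin
wallace
moreno
west
cole
hayes
bryant
herrera
gibson
ellis
tran
medina
aguilar
stevens
murray
ford
castro
marshall
owens
harrison
fernandez
mcdonald
woods
washington
kennedy
wells
vargas
henry
chen
freeman
webb
tucker
guzman
burns
crawford
olson
simpson
porter
hunter
gordon
mendez
silva
shaw
snyder
mason
dixon
munoz
hunt
hicks
holmes
palmer
wagner
black
robertson
boyd
rose
stone
salazar
fox
warren
mills
meyer
rice
schmidt
daniels
ferguson
nichols
stephens
soto
weaver
ryan
gardner
payne
grant
dunn
kelley
spencer
hawkins
arnold
pierce
vazquez
hansen
peters
santos
hart
bradley
knight
elliott
cunningham
duncan
armstrong
hudson
carroll
lane
riley
andrews
alvarado
ray
delgado
berry
perkins
hoffman
johnston
matthews
pena
richards
contreras
willis
carpenter
lawrence
sandoval
guerrero
cortez
carrillo
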