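# German pathology-flavoured filler vocabulary for the synthetic corpus.
# No real patient text; chosen so that no default query label matches any
# word (the generator additionally screens against the active model).
Das
eingesandte
Gewebematerial
zeigt
regelrechte
Schleimhautanteile
entzündliche
Veränderungen
histologisch
unauffällige
Architektur
mehrfragmentiertes
Exzidat
mit
glatter
Oberfläche
teils
hämorrhagisch
durchsetztes
Stroma
fibrosierte
Areale
sowie
vereinzelte
Drüsenstrukturen
kein
Anhalt
für
Malignität
im
vorliegenden
Schnittgut
chronische
Begleitentzündung
geringer
Ausprägung
die
Beurteilung
erfolgt
am
Paraffinschnitt
nach
HE-Färbung
ergänzende
Stufenschnitte
wurden
angefertigt
das
Präparat
wurde
vollständig
eingebettet
makroskopisch
gut
abgrenzbare
Läsion
von
derber
Konsistenz
angrenzendes
Fettgewebe
reaktive
Lymphknoten
ödematöse
Mukosa
fokale
Epithelhyperplasie
basale
Zellschicht
erhalten
Befund
kontrollbedürftig
klinische
Korrelation
empfohlen
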