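# Default English grapheme-phoneme correspondence rules (monosyllables).
# Columns: pattern <TAB> class <TAB> position <TAB> context <TAB> phoneme <TAB> precedence
#   pattern:  uppercase letters, "." marks the gap of a discontinuous split
#             vowel grapheme (head before ".", word-final silent tail after).
#   position: any | onset (no vowel letter precedes) | coda (a vowel letter
#             precedes) | initial (word-initial) | final (word-final)
#   context:  "-" or next=SET / prev=SET over adjacent raw letters ("#" = word edge)
#   phoneme:  canonical IPA from the phoneme inventory
#   precedence: rank used to break ties among equal-length, equally specific rules
#
# Single-letter consonants
B	consonant	any	-	b	50
C	consonant	any	-	k	50
C	consonant	any	next=E,I,Y	s	10
D	consonant	any	-	d	50
F	consonant	any	-	f	50
G	consonant	any	-	g	50
G	consonant	any	next=E,I,Y	ʤ	10
H	consonant	any	-	h	50
J	consonant	any	-	ʤ	50
K	consonant	any	-	k	50
L	consonant	any	-	l	50
M	consonant	any	-	m	50
N	consonant	any	-	n	50
P	consonant	any	-	p	50
Q	consonant	any	-	k	50
R	consonant	any	-	r	50
S	consonant	any	-	s	50
T	consonant	any	-	t	50
V	consonant	any	-	v	50
W	consonant	any	-	w	50
X	consonant	any	-	z	50
Y	consonant	any	next=A,E,I,O,U	j	10
Z	consonant	any	-	z	50
# Single-letter vowels
A	vowel	any	-	æ	50
E	vowel	any	-	ɛ	50
I	vowel	any	-	ɪ	50
O	vowel	any	-	ɒ	50
U	vowel	any	-	ʌ	50
Y	vowel	any	-	aɪ	50
# Multi-letter consonant graphemes
SH	consonant	any	-	ʃ	40
CH	consonant	any	-	ʧ	40
TH	consonant	any	-	θ	40
PH	consonant	any	-	f	40
WH	consonant	onset	-	w	40
CK	consonant	coda	-	k	40
NG	consonant	coda	next=#	ŋ	40
LL	consonant	any	-	l	40
SS	consonant	any	-	s	40
FF	consonant	any	-	f	40
ZZ	consonant	any	-	z	40
GN	consonant	onset	-	n	40
KN	consonant	onset	-	n	40
PS	consonant	onset	-	s	40
WR	consonant	onset	-	r	40
GE	consonant	final	-	ʤ	40
CE	consonant	final	-	s	40
TCH	consonant	final	-	ʧ	30
# Multi-letter vowel graphemes
AI	vowel	any	-	eɪ	40
AY	vowel	any	-	eɪ	40
AU	vowel	any	-	ɔː	40
AW	vowel	any	-	ɔː	40
EA	vowel	any	-	iː	40
EE	vowel	any	-	iː	40
EI	vowel	any	-	eɪ	40
EU	vowel	any	-	uː	40
EW	vowel	any	-	uː	40
IE	vowel	any	-	aɪ	40
OA	vowel	any	-	əʊ	40
OE	vowel	any	-	əʊ	40
OI	vowel	any	-	ɔɪ	40
OY	vowel	any	-	ɔɪ	40
OO	vowel	any	-	uː	40
OU	vowel	any	-	aʊ	40
OW	vowel	any	-	aʊ	40
UE	vowel	any	-	uː	40
UI	vowel	any	-	uː	40
AR	vowel	any	-	ɑː	40
ER	vowel	any	-	ɜː	40
IR	vowel	any	-	ɜː	40
OR	vowel	any	-	ɔː	40
UR	vowel	any	-	ɜː	40
IGH	vowel	any	-	aɪ	30
# Split (discontinuous) vowel graphemes; tail is word-final E or UE
A.E	vowel	any	-	eɪ	20
E.E	vowel	any	-	iː	20
I.E	vowel	any	-	aɪ	20
O.E	vowel	any	-	əʊ	20
U.E	vowel	any	-	uː	20
A.UE	vowel	any	-	æ	20
I.UE	vowel	any	-	iː	20
U.UE	vowel	any	-	uː	20
EU.E	vowel	any	-	uː	20
AI.E	vowel	any	-	eɪ	20
AU.E	vowel	any	-	əʊ	20
IE.E	vowel	any	-	iː	20
OA.E	vowel	any	-	ɔː	20
OU.E	vowel	any	-	uː	20
UI.E	vowel	any	-	aɪ	20
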