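# General-English monosyllable phoneme inventory.
# Columns: ipa <TAB> class (vowel|consonant) <TAB> aliases (comma-separated, optional).
# Aliases are alternative surface spellings accepted by the tokenizer and
# normalized to the canonical ipa form (transcription dialects differ).
p	consonant
b	consonant
t	consonant
d	consonant
k	consonant
g	consonant	ɡ
m	consonant
n	consonant
ŋ	consonant
f	consonant
v	consonant
θ	consonant
ð	consonant
s	consonant
z	consonant
ʃ	consonant
ʒ	consonant
h	consonant
ʧ	consonant	tʃ,t̠ʃ
ʤ	consonant	dʒ,d̠ʒ
l	consonant
r	consonant	ɹ
w	consonant
j	consonant
ɪ	vowel
ɛ	vowel
æ	vowel
ʌ	vowel
ɒ	vowel
ʊ	vowel
ə	vowel
i	vowel
u	vowel
e	vowel
o	vowel
a	vowel
iː	vowel
uː	vowel
ɔː	vowel
ɑː	vowel
ɜː	vowel	əː
eɪ	vowel
aɪ	vowel
ɔɪ	vowel
aʊ	vowel
əʊ	vowel	oʊ
ɪə	vowel
eə	vowel
ʊə	vowel
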