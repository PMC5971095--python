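# Methods

## The three-stage model and what the package measures

Skilled adult readers produce strikingly different pronunciations when
asked to read pronounceable nonwords aloud. `graphovar` operationalizes a
three-stage account of nonlexical reading: **graphemic parsing** (segmenting
the letter string into graphemes, e.g. SHOIL → SH, OI, L), **phoneme
assignment** (mapping each grapheme to a phoneme, e.g. /ʃ/, /ɔɪ/, /l/), and
**phoneme blending** (fusing the phonemes into a syllable). Blending is
represented in the data model but not analysed: skilled readers essentially
never fail to blend, so the package quantifies variability at the first two
stages only.

A grapheme is defined as the written representation of a single phoneme, so
a response whose phoneme count equals the grapheme count of the stimulus's
standard parse reflects a **standard parsing**; any other count reflects a
**nonstandard parsing** (a grapheme was inserted, omitted, or a multi-letter
grapheme was read as its constituent letters). This count-based criterion is
deliberately the *only* criterion for standardness, even when an
equal-length alternative segmentation exists; it is an operational
definition, and its coarseness is a known limitation (see below). For
standard-parse responses the graphemes and phonemes pair off positionally
one to one, which makes per-subject grapheme→phoneme tallies well defined.
An assignment is **standard** when it equals the inventory's standard
phoneme for that grapheme — the phoneme corresponding to the grapheme most
often in English monosyllables, position and context taken into account.

Assignment variability is quantified with Shannon entropy in bits,

    H = −Σᵢ pᵢ log₂ pᵢ,

where pᵢ is the proportion of assignments of phoneme *i* to the grapheme in
question. H = 0 means unanimity; log₂k is the maximum over k observed
phonemes. H is computed per (subject, grapheme) cell, summarized per
subject as a mean over that subject's eligible graphemes, and per grapheme
across subjects in two flavours: *pooled* (all subjects' assignments lumped
into one distribution — the headline measure, matching "proportion of
participants assigning the grapheme a particular phoneme") and
*mean-over-subjects* (average of each subject's own H, which weights
subjects equally and is insensitive to between-subject disagreement about
which single phoneme to use). Both are reported because published summaries
of this kind of data have used both framings.

## Phoneme inventory and tokenization

The shipped inventory is a General-English monosyllable set: 24 consonants
(including /ʧ ʤ ŋ θ ð ʃ ʒ/) and ~25 vowel symbols (short vowels, the long
vowels /iː ɜː ɔː ɑː uː/, the diphthongs /eɪ aɪ ɔɪ aʊ əʊ ɪə eə ʊə/, and the
plain /i u e o a/ that appear in looser transcription practice).
Transcriptions are tokenized by greedy longest match after stripping
slashes, brackets, whitespace and stress marks (monosyllables carry no
contrastive stress) and normalizing `:` to `ː`. The inventory is
prefix-ambiguous only between a multi-character phoneme and its first
character, so greedy matching is exact; diphthongs and affricates are
single phonemes, which is what the grapheme definition requires. Two-glyph
affricate spellings (tʃ, dʒ), script ɡ and ɹ are accepted as aliases and
normalized. An unknown symbol aborts tokenization with its offset rather
than being skipped — silently dropping a symbol would corrupt the phoneme
count, which is the core measure; such records are flagged unanalysable and
excluded from all denominators, exactly like absent responses.

## The GPC rule table

No complete grapheme inventory for this kind of analysis has been published,
so the package ships a DRC-style English rule table (87 rules): all single
letters, the common consonant digraphs (SH, CH, TH, PH, WH, CK, NG, LL, SS,
FF, ZZ, GN, KN, PS, WR, GE, CE, TCH), the vowel digraphs (AI, AU, AW, EA,
EE, EI, EU, EW, IE, OA, OE, OI, OY, OO, OU, OW, UE, UI, AR, ER, IR, OR, UR,
IGH), and fifteen split vowel graphemes with word-final silent tails: A.E,
E.E, I.E, O.E, U.E plus the three-letter-tail family A.UE, I.UE, U.UE,
EU.E, AI.E, AU.E, IE.E, OA.E, OU.E, UI.E. Rules carry a position constraint
(word-initial GN/KN/PS/WR, word-final GE/CE/TCH, post-vocalic CK/NG), an
optional adjacent-letter context (C and G soften before E/I/Y; Y is /j/
before a vowel letter and /aɪ/ otherwise; NG applies only word-finally so
that -NGE words keep their final GE), and a precedence rank. Each rule's
class matches its phoneme's class (vowel graphemes map to vowel phonemes).
X maps to the single phoneme /z/: the common /ks/ reading is two phonemes
and would break the one-grapheme-one-phoneme bijection the analysis rests
on, so stimuli containing X are best avoided (the generator never emits
them in positions where /ks/ would be natural). Published lists of the
eligible graphemes in this paradigm contain an apparent duplication ("O"
twice alongside "O. E"); the shipped table resolves this as O and O.E.

The standard phonemes in the table are editorial choices for the majority
reading in monosyllables; `derive_standard_assignments` re-derives them by
majority over any aligned spelling→IPA lexicon the user supplies. Counts
are by word type, not token frequency (token counts would need a frequency
source and published practice does not specify one). Majority candidates
are restricted to phonemes of the grapheme's class, ties break by the
phoneme's summed count across all graphemes and then lexicographic IPA —
deterministic and auditable. Words whose grapheme count differs from their
phoneme count cannot be aligned one-to-one and are skipped with a log
message. The operation is idempotent for a fixed lexicon.

## Standard parsing algorithm

1. **Split-vowel pre-binding.** Scan the split rules for a head matching
   somewhere in the word and a tail (E or UE) at the word end, separated by
   one or two intervening consonant letters. Among candidates, prefer the
   longest head, then the leftmost. One exception governs the competition
   for the final silent E: if there are exactly two intervening consonants
   and the last of them forms a word-final consonant grapheme with the E
   (GE or CE), the final grapheme wins and the split vowel is not bound.
   This yields DONGE → D, O, N, GE and PONCE → P, O, N, CE while keeping
   WOUGE → W, OU.E, G (one intervening consonant) and STOARSE → S, T,
   OA.E, R, S (SE is not a grapheme).
2. **Maximal munch.** The remaining letters are segmented left to right:
   at each position the applicable rule with the longest pattern wins, with
   context-specific rules beating generic ones at equal length and the
   precedence rank breaking any remainder. Position and context conditions
   are evaluated against the raw letter string.

The two intervening-consonant limits (1–2) are the smallest that cover the
attested split-grapheme repertoire (U.UE across SQ, OA.E across RS). With
the shipped table every A–Z letter has a context-free rule, so every letter
string parses; NoParse can only arise under user-supplied restricted
inventories.

`enumerate_parses` explores every binding (including ones the standard
parse rejects) and every contiguous segmentation, returns the standard
parse first, and sets a truncation flag at `max_count`. It is validated
exhaustively against a 2^(n−1) split-point oracle on a toy inventory.

## The response aligner (diagnostic)

`infer_parse` reconstructs the segmentation a response most plausibly
implies: every candidate parse is aligned to the response phonemes by
dynamic programming with costs match 0, nonstandard substitution 1
(1.25 when the phoneme's vowel/consonant class disagrees with the
grapheme's — a rarer reading), grapheme omission 2, phoneme insertion 2.5;
ties break toward the parse sharing most elements with the standard parse.
Insertions are priced above omissions so that an unsupported inserted
phoneme is dispreferred to reading a multi-letter vowel grapheme as its
constituent letters: with equal prices, a response like /səʊwəθ/ for PSOATH
would tie between "two insertions into the standard parse" and the
letter-by-letter reading of OA that such responses actually indicate. The
aligner is a diagnostic: the headline nonstandard-parsing counts use only
the phoneme-count criterion, since published counts are defined that way
and an aligner-based classification would be a different (finer) measure.

## Synthetic data generator

`simulate_responses` emulates the study conditions end to end:
45 subjects × 412 monosyllabic nonwords, 2.3% missing responses. Nonwords
are composed onset + nucleus + coda from the inventory's patterns (35% of
them built around a split vowel grapheme) and filtered so the standard
pronunciation tokenizes back to exactly one phoneme per grapheme. Each
subject draws a parse-perturbation propensity uniformly from 3.16–36.65%
and a nonstandard-assignment mass uniformly from 9–31% — the observed
between-subject ranges for the two stages. A perturbed trial alters the
*parse* (split a multi-letter grapheme into its letters with probability
.60, omit a grapheme .25, insert /ə w j/ between graphemes .15; splits
target vowel graphemes 85% of the time, mirroring the observed asymmetry);
every grapheme of the resulting parse then receives a phoneme from the
subject's per-grapheme categorical distribution (standard phoneme with
probability 1−q, the rest spread Dirichlet-style over three same-class
alternatives). In the rare case where drawn phonemes would coalesce under
tokenization (e.g. an inserted /ə/ fusing with a following /ʊ/), the draw
is retried and, failing that, the trial reverts to the fully standard
pronunciation with the ledger marked `repaired`; this keeps the
perturbed ⇔ nonstandard-classification equivalence exact.

What the generator does **not** model: item-level difficulty (all items are
equally exposed to a subject's propensity, so item rates vary only
binomially, whereas real items range from 0% to >90% nonstandard), lexical
analogy and frequency effects, correlated rule sets across subjects, and
any blending failures. Consequently the simulated *overall* rates sit near
the midpoints of the per-subject ranges (~20%), not at the overall values a
skewed real panel produces (~12% parsing, ~9% assignment). Passing
recovery tests therefore show that the pipeline measures what the
generator encodes — not that real data look like the simulation.

`recover_parameters` reruns the whole pipeline on simulated records and
compares per-subject estimates with ledger truth within three binomial
standard errors at each subject's own denominator; it also reports the mean
plug-in entropy bias over tally cells, which is negative at small counts
(the plug-in estimator underestimates H — visible at the 4-occurrence
eligibility floor and vanishing by ~100 occurrences).

## Numerical and design choices

* Entropy uses log base 2 with the 0·log 0 = 0 convention
  (`scipy.stats.entropy(base=2)` behind the module surface); values are
  kept at full precision internally and rounded (2 dp) only at the
  presentation layer.
* Eligibility for assignment analyses requires a grapheme to occur at
  least 4 times in *every* subject's standard-parse responses
  (`min_per_subject`, configurable); subject-level entropy cells
  additionally honour `min_cell` (default 1, i.e. global eligibility only).
* Zero-denominator rate cells are reported as missing, never as 0%.
* Duplicate (subject, nonword) rows in input tables are logged and the
  last wins; nonwords are uppercased on read.
* Reports are byte-deterministic for fixed inputs and configuration; the
  provenance block carries a config digest and package version, no
  timestamps.
* Default problem sizes throughout (45 × 412 simulation, 10 recovery
  seeds, length ≤ 6 oracle sweeps) were chosen to exercise the full study
  geometry while keeping any single check in the tens of seconds.

## Known limitations

* The count-based standardness criterion cannot detect compensating
  errors (an omission plus an insertion in one response looks standard).
* The shipped rule table is an editorial reconstruction; analyses of real
  data are only as faithful as the inventory supplied, and overall rates
  are sensitive to it.
* The aligner's costs are heuristic defaults, configurable but not fitted.
* Split-grapheme binding assumes monosyllables; no syllabification or
  stress is modelled, and multisyllabic stimuli are out of scope.
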