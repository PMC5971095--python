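# graphovar

Grapheme-level analysis of why skilled adult readers are so variable when
they read nonwords aloud.

When undergraduates read pronounceable nonwords such as SHOIL or GNEUTH,
a single item can evoke two dozen different pronunciations across a group.
`graphovar` decomposes that variability along a three-stage model of
nonlexical reading — **graphemic parsing** (SHOIL → SH, OI, L), **phoneme
assignment** (SH → /ʃ/, OI → /ɔɪ/, L → /l/), and **phoneme blending** — and
quantifies the first two stages (blending failures are essentially absent
in skilled readers):

* a response is a **standard parsing** iff its phoneme count equals the
  grapheme count of the stimulus's standard parse; otherwise nonstandard;
* for standard-parse responses, graphemes and phonemes pair off one to
  one, giving per-subject grapheme→phoneme **assignment tallies**; an
  assignment is standard iff it is the grapheme's majority phoneme in
  English monosyllables (position and context taken into account);
* assignment variability per (subject, grapheme) and per grapheme across
  subjects is measured with Shannon entropy, H = −Σᵢ pᵢ log₂ pᵢ (bits),
  where pᵢ is the proportion of assignments of phoneme i; parsing
  variability as % nonstandard per subject and per nonword.

The package ships a DRC-style English GPC rule table (87 rules, including
split vowel graphemes such as O.E in SCROME and A.UE in THAQUE), an IPA
phoneme inventory with a greedy longest-match tokenizer, a dynamic
programming aligner that reconstructs the parse a response implies, a
synthetic reader-response generator with a ground-truth ledger for
end-to-end validation, and a `graphovar` command line. It analyses any
subject × nonword response table with columns
`subject_id, nonword, transcription` (CSV/TSV; a column map handles other
layouts).

## Worked example

```python
>>> from graphovar import (default_inventory, standard_parse, entropy,
...                        classify_parsing, ResponseRecord)
>>> inv = default_inventory()
>>> str(standard_parse("GNEUTH", inv))
'GN+EU+TH'
>>> c = classify_parsing(ResponseRecord("s1", "GNEUTH", "/gwɛnθ/"), inv)
>>> c.n_graphemes, c.n_phonemes, c.status
(3, 5, 'nonstandard')
>>> round(entropy({"ʧ": 3, "k": 11, "s": 1, "ʃ": 2, "θ": 1}), 2)
1.68
```

GNEUTH parses into three graphemes (GN, EU, TH), so the five-phoneme
response /gwɛnθ/ — the reader treated G and N as separate graphemes and
split EU — is a nonstandard parsing. The entropy line is a reader who
translated CH as /ʧ/ three times, /k/ eleven times, /s/ once, /ʃ/ twice
and /θ/ once: 1.68 bits of assignment variability for a single grapheme
(0 would mean perfect consistency).

From the shell, an end-to-end run on synthetic data:

```bash
$ graphovar parse SHOIL
SHOIL   SH+OI+L /ʃɔɪl/
$ graphovar simulate --seed 3 --subjects 45 --nonwords 412 -o responses.tsv
$ graphovar report responses.tsv -o report/
```

`report/` then contains `summary.json` (bookkeeping and overall rates;
this run prints `n_potential_responses: 18540`,
`pct_nonstandard_parsings: 21.3852`)
plus per-subject and per-item rate tables, the assignment tally, entropy
tables, and distinct-response counts — one CSV per figure-style summary.

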