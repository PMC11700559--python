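# Default stop-phrase list: text known to be irrelevant to daily-dose
# extraction, removed after synonym expansion.  One phrase per line, matched
# case-insensitively on word boundaries.  Phrases must never contain digits —
# the loader enforces this so numerals always survive normalization.
by mouth
orally
with food
with water
with meals
with a meal
with or without food
on an empty stomach
please
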