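# Default synonym table: surface form <TAB> canonical form.
# Matched case-insensitively on word boundaries, longest surface form first.
# Curated for common English sig abbreviations; the canonical side is the
# vocabulary the extractor's grammars are written against.
times a day	times daily
times per day	times daily
times each day	times daily
as needed	prn
at bedtime	nightly
every night	nightly
each day	every day
every morning at breakfast	every morning
tablets	tablet
tabs	tablet
tab	tablet
capsules	capsule
caps	capsule
cap	capsule
pills	pill
puffs	puff
drops	drop
milliliters	ml
milliliter	ml
cc	ml
milligrams	mg
milligram	mg
micrograms	mcg
microgram	mcg
ug	mcg
weeks	week
wks	week
wk	week
months	month
mos	month
mo	month
days	day
hours	hour
hrs	hour
hr	hour
bid	2 times daily
tid	3 times daily
qid	4 times daily
twice	2 times
thrice	3 times
once	1 time
qdaily	every day
qday	every day
qd	every day
qhs	nightly
qod	every other day
qam	every morning
qpm	every evening
po	by mouth
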