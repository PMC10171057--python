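# Default intracranial-hemorrhage keyword lexicon (14 entries).
# Format: stem<TAB>kind, kind in {word_stem, abbreviation}.
# word_stem entries match as token prefixes (so "hemorrhage" also covers
# "hemorrhages"); abbreviations match only as whole tokens.
hemorrhage	word_stem
hematoma	word_stem
hemorrhagic	word_stem
intracerebral	word_stem
subarachnoid	word_stem
epidural	word_stem
subdural	word_stem
intraventricular	word_stem
parenchymatous	word_stem
episubdural	word_stem
sah	abbreviation
edh	abbreviation
sdh	abbreviation
ich	abbreviation
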