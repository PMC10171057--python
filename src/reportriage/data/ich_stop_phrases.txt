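# Default stop-phrase lexicon (33 entries): formulaic report sentences whose
# presence implies absence of intracranial hemorrhage.  One phrase per line;
# matching is case- and whitespace-insensitive at token level.
#
# The seven phrases below are real report boilerplate.
foci of pathological density of the brain matter are not found
CT data for intracranial hematoma and brain contusion are not obtained
signs of intracranial hemorrhage are not found
in the obtained images, foci of pathological density in the brain matter are not determined
CT signs of intracranial hematoma, cranial bone fractures, other focal and volumetric brain matter alterations are not detected
fresh hemorrhages or ischemic changes in the brain were not detected
data on intracranial hematoma in this investigation was not found
#
# SYNTHESIZED: the 26 phrases below were composed in the same formulaic style
# to round out the lexicon; they are synthetic, not transcribed boilerplate.
no CT evidence of intracranial hemorrhage
no signs of acute intracranial hemorrhage are determined
CT signs of subarachnoid hemorrhage are not detected
no data for subdural or epidural hematoma
intracranial hematoma is not visualized
no evidence of intraventricular hemorrhage
acute hemorrhagic changes are not identified
no fresh foci of pathological density are detected in the brain matter
signs of epidural hematoma are not found
signs of subdural hematoma are not found
CT data for subarachnoid hemorrhage are not obtained
no convincing CT data for intracranial hemorrhage
hemorrhagic foci in the brain matter are not determined
areas of pathologically increased density are not found in the brain matter
no signs of hemorrhage into the ventricular system
no evidence of acute subdural hematoma
no evidence of acute epidural hematoma
intracerebral hematoma is not determined
no foci of hemorrhagic density are identified
CT picture without signs of intracranial hemorrhage
signs of SAH are not detected
no CT signs of intracranial hematoma are found
hyperdense foci in the brain matter are not visualized
no data for hemorrhagic transformation
brain matter without foci of pathological density
signs of parenchymatous hemorrhage are not found
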