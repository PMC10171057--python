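{
  "name": "en",
  "comment": "Synthetic English paraphrases of brain-CT report boilerplate; a bank for another language can be substituted with the same keys.",
  "facilities": [
    "City Clinical Hospital No. 1",
    "City Clinical Hospital No. 7",
    "City Clinical Hospital No. 23",
    "Emergency Care Hospital",
    "Regional Diagnostic Center",
    "University Clinic"
  ],
  "boilerplate": [
    "Non-contrast CT of the brain was performed.",
    "Series of axial tomograms of the brain were obtained.",
    "Multislice CT of the brain without intravenous contrast enhancement."
  ],
  "neutral_findings": [
    "The ventricular system is of usual shape and size.",
    "Basal cisterns are differentiated.",
    "Moderate age-related involutional changes of the brain matter.",
    "The median structures are not displaced.",
    "Single calcified focus in the right basal ganglia.",
    "Periventricular zones of reduced density consistent with chronic ischemia.",
    "Bone structures of the cranial vault are intact."
  ],
  "positive_findings": [
    "Acute subdural hematoma along the right convexity up to 12 mm thick.",
    "Acute subdural hematoma along the left convexity up to 8 mm thick.",
    "Subarachnoid hemorrhage in the basal cisterns and along the convexital sulci.",
    "Intracerebral hematoma in the left temporal lobe with perifocal edema.",
    "Intracerebral hematoma in the right frontal lobe with perifocal edema.",
    "Epidural hematoma in the right frontal region adjacent to the fracture line.",
    "Intraventricular hemorrhage with blood in the occipital horns of both lateral ventricles.",
    "Hemorrhagic contusion foci in both frontal lobes.",
    "Parenchymatous hemorrhage in the region of the right basal ganglia.",
    "A small zone of hemorrhagic impregnation of the brain tissue in the left parietal lobe.",
    "Massive SAH with blood along the tentorium."
  ],
  "positive_conclusions": [
    "CT picture of acute subdural hematoma.",
    "CT picture of acute subarachnoid hemorrhage.",
    "CT picture of intracerebral hematoma.",
    "Acute intracranial hemorrhage.",
    "CT picture of epidural hematoma.",
    "CT signs of intraventricular hemorrhage."
  ],
  "distractor_findings": [
    "Hematoma of the soft tissues of the scalp in the parietal region.",
    "Hemorrhage into the facial soft tissues.",
    "Subgaleal hematoma in the left frontotemporal region.",
    "Hematoma of the soft tissues of the orbit on the right."
  ],
  "distractor_conclusions": [
    "Hematoma of the scalp soft tissues.",
    "Hemorrhage into the soft tissues of the face.",
    "Subgaleal hematoma."
  ],
  "negative_conclusions": [
    "No acute pathology of the brain.",
    "Age-related changes of the brain matter.",
    "CT picture of chronic cerebral ischemia.",
    "Brain CT without acute focal pathology."
  ]
}
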