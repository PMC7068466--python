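{
  "direct_phrases": [
    "acute low back pain",
    "acute lbp",
    "acute low bp",
    "acute back pain"
  ],
  "direct_sentence_templates": [
    "patient presents with {phrase} after lifting a heavy box at work",
    "assessment {phrase} of sudden onset yesterday",
    "he reports {phrase} since a fall on the stairs",
    "she describes {phrase} that began this morning",
    "impression {phrase} likely muscular strain",
    "new onset {phrase} following yard work"
  ],
  "paraphrase_sentences": [
    "shooting pain down into the lower extremities",
    "limited spine range of motion on exam",
    "vertebral tenderness to palpation noted",
    "diffuse pain in lumbar muscles after lifting",
    "sudden onset lumbar spasm while moving furniture",
    "sharp lumbosacral strain following a fall",
    "paraspinal muscle spasm with guarding on flexion"
  ],
  "support_sentences": [
    "prescribed muscle relaxant and rest",
    "started flexeril ten milligrams at bedtime",
    "cyclobenzaprine prescribed for spasm",
    "naproxen twice daily with food",
    "recommend rtw full duty quick recovery expected",
    "back brace dispensed for comfort",
    "obtain lumbar spine mri if no improvement",
    "recommendation rtw visit in one week",
    "advised ice and early mobilization"
  ],
  "chronic_sentences": [
    "chronic low back pain stable on current regimen",
    "followup for chronic lbp managed conservatively",
    "longstanding low back pain unchanged from prior visits",
    "chronic lumbar degenerative disease followup today"
  ],
  "negation_templates": [
    "denies {phrase}",
    "no evidence of {phrase}",
    "no {phrase} today",
    "patient denies {phrase} or radiculopathy",
    "{phrase} ruled out on examination",
    "{phrase} unlikely given benign exam",
    "negative for {phrase}"
  ],
  "background_sentences": [
    "patient seen for annual physical examination",
    "blood pressure well controlled on lisinopril",
    "review of systems otherwise negative",
    "denies fever chills or night sweats",
    "continue current medications as prescribed",
    "diet and exercise counseling provided",
    "type two diabetes followup hemoglobin stable",
    "seasonal allergies managed with loratadine",
    "mild intermittent asthma uses albuterol as needed",
    "immunizations up to date",
    "patient reports good energy and appetite",
    "followup in three months or sooner if needed",
    "knee pain improved with physical therapy",
    "shoulder range of motion full and painless",
    "no distress noted on examination",
    "cardiovascular exam regular rate and rhythm",
    "lungs clear to auscultation bilaterally",
    "abdomen soft nontender without masses",
    "skin warm and dry without rashes",
    "neurologic exam grossly intact",
    "labs reviewed with patient today",
    "cholesterol panel improved since last visit",
    "smoking cessation discussed patient precontemplative",
    "alcohol use social no concerns",
    "sleep quality fair recommends sleep hygiene",
    "headaches occasional relieved with ibuprofen",
    "gastroesophageal reflux controlled with omeprazole",
    "thyroid function within normal limits",
    "weight stable since previous encounter",
    "depression screening negative today",
    "vision and hearing screening unremarkable",
    "referred to dermatology for skin check",
    "discussed colonoscopy screening guidelines",
    "influenza vaccine administered today",
    "urinary symptoms denied",
    "ankle sprain healing well with bracing",
    "wrist pain resolved since last visit",
    "elbow tendinitis improving with rest",
    "hypertension followup medication adherent",
    "pressure reading one twenty over eighty"
  ],
  "other_icd_codes": ["E11.9", "I10", "J06.9", "Z00.00", "M25.561", "K21.9"]
}
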