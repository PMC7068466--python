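# Illustrative curated n-gram lexicon (n = 1..5) for the FeatEng variant,
# built from acute-LBP diagnosis, related-condition, medication and
# return-to-work recommendation phrases. Entries are preprocessed on load.
muscle spasm lower back
acute lbp flare
been having acute back pain
acute midline lbp
sports acute bilateral lbp
acute low back pain
acute lbp
acute back pain
acute low bp
gait abnormality
showed significant disk herniation
intermittent sciatica
spinal stenosis
back pain flare prescribed flexeril
cyclobenzaprine
flexeril
naproxen for acute low back
naproxen
prescribed muscle relaxant
muscle relaxant
back brace for back pain
back brace
obtain lumbar spine mri
lumbar spine mri
recommendation rtw visit
rtw full duty quick
rtw
shooting pain down into
pain down into the lower
lower extremities
limited spine range of motion
vertebral tenderness
diffuse pain in lumbar muscles
lumbar spasm
lumbosacral strain
paraspinal muscle spasm
sudden onset
early mobilization
chronic low back pain
low back pain
back pain
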