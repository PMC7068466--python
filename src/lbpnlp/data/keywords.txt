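# Acuity keyword phrases, one per line (preprocessed like note text on load)
acute low back pain
acute lbp
acute low bp
acute back pain
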