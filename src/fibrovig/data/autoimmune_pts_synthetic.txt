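# Synthetic stand-in list of MedDRA preferred terms under the HLGT
# "Autoimmune disorders". The licensed MedDRA hierarchy cannot be
# redistributed; supply your own PT list for production analyses.
Rheumatoid arthritis
Systemic lupus erythematosus
Psoriatic arthritis
Psoriasis
Ankylosing spondylitis
Sjogren's syndrome
Ulcerative colitis
Crohn's disease
Juvenile idiopathic arthritis
Dermatomyositis
Polymyositis
Systemic sclerosis
Autoimmune hepatitis
Vasculitis
Mixed connective tissue disease
Autoimmune thyroiditis
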