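carcinoma	cancer
tumor	tumour
renal	kidney
cardiac	heart
hepatic	liver
pulmonary	lung
gastric	stomach
cerebral	brain
cutaneous	skin
haemorrhage	hemorrhage
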