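>glucagon human glucagon (29 aa)
HSQGTFTSDYSKYLDSRRAQDFVQWLMNT
>GLP1 human glucagon-like peptide-1 (7-36)
HAEGTFTSDVSSYLEGQAAKEFIAWLVKGR
>GIP human glucose-dependent insulinotropic polypeptide (1-42)
YAEGTFISDYSIAMDKIHQQDFVNWLLAQKGKKNDWKHNITQ
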