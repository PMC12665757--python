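token_pattern,delta_mass_Da,kd_value,charge,polar_flag,notes
"[K (yE-C16)]",367.53,3.5,0.0,0,"gamma-Glu spacer + palmitoyl on Lys side chain; mass increment chemistry-derived estimate"
"[K (yE-C18)]",395.58,3.8,0.0,0,"gamma-Glu spacer + stearoyl on Lys side chain; estimate"
"[K (eK-eK-yE-C20DA)]",709.96,3.0,-1.0,0,"epsilon-Lys x2 + gamma-Glu spacer + C20 diacid on Lys; one free carboxylate; estimate"
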