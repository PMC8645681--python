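# Fractional tissue composition (volume fractions of water, neutral lipid,
# phospholipid) for the tissue-composition Kp method; literature-typical
# human values.
adipose:  {f_water: 0.18,  f_neutral_lipid: 0.79,   f_phospholipid: 0.002}
bone:     {f_water: 0.439, f_neutral_lipid: 0.074,  f_phospholipid: 0.0011}
brain:    {f_water: 0.77,  f_neutral_lipid: 0.051,  f_phospholipid: 0.0565}
gut:      {f_water: 0.718, f_neutral_lipid: 0.0487, f_phospholipid: 0.0163}
heart:    {f_water: 0.758, f_neutral_lipid: 0.0115, f_phospholipid: 0.0166}
kidney:   {f_water: 0.783, f_neutral_lipid: 0.0207, f_phospholipid: 0.0162}
liver:    {f_water: 0.751, f_neutral_lipid: 0.0348, f_phospholipid: 0.0252}
lung:     {f_water: 0.811, f_neutral_lipid: 0.003,  f_phospholipid: 0.009}
muscle:   {f_water: 0.76,  f_neutral_lipid: 0.0238, f_phospholipid: 0.0072}
skin:     {f_water: 0.718, f_neutral_lipid: 0.0284, f_phospholipid: 0.0111}
spleen:   {f_water: 0.788, f_neutral_lipid: 0.0201, f_phospholipid: 0.0198}
pancreas: {f_water: 0.664, f_neutral_lipid: 0.0403, f_phospholipid: 0.0093}
plasma:   {f_water: 0.96,  f_neutral_lipid: 0.0035, f_phospholipid: 0.00225}
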