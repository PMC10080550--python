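# Packaged preset: 19-residue SilE fragment (residues 107-125), ESI-MS
# titration of 100 uM peptide at the four Ag+:peptide ratios of the study
# design.  Ground-truth stepwise constants: the tight first site at the
# sub-micromolar literature value and the weaker second site in the tens of
# micromolar.  Noiseless by design.
name: sp3-paper
kind: ms
sequence: AMNEHERAAVAHEFMNNGQ
numbering_offset: 107
kd1_um: 0.2
kd2_um: 24.5
p_total_um: 100.0
ratios: [0.0, 0.5, 1.0, 2.0]
z_range: [2, 3]
n_max: 3
charge_weights: {2: 0.6, 3: 0.4}
dimer_fraction: 0.35
ag3_fraction: 0.05
noise_cv: 0.0
seed: 1722
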