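# Packaged preset: 16-residue SilE fragment (residues 77-92), homonuclear
# TOCSY titration at the five Ag+:peptide ratios of the study design, with a
# phenomenological two-mode path whose direction change sits at 0.5
# equivalents.  Noiseless: these are the defining study conditions, not a
# noise benchmark.
name: sp2-paper
kind: nmr
sequence: ADAHQKMVESHQRMMG
numbering_offset: 77
spectrum_type: TOCSY
ratios: [0.0, 0.1, 0.5, 3.0, 10.0]
mode: piecewise
break_ratio: 0.5
noise_sd: 0.0
seed: 1722
# Two-mode movers, protein numbering.  pre = ppm displacement (f1, f2)
# accumulated linearly from ratio 0 to the break; post = additional
# displacement from the break to the final ratio, in a different direction.
# The His/Met face residues move most; 84Val's amide/H-gamma cross-peak is
# the showcase trajectory.
movers:
  80: {atoms: [H, HA], pre: [0.030, 0.012], post: [-0.010, 0.035]}
  83: {atoms: [H, HA], pre: [0.024, 0.018], post: [0.030, -0.025]}
  84: {atoms: [H, HG], pre: [0.040, 0.000], post: [0.010, 0.045]}
  87: {atoms: [H, HA], pre: [0.050, 0.020], post: [-0.020, 0.040]}
  90: {atoms: [H, HA], pre: [0.080, 0.050], post: [0.060, -0.050]}
  91: {atoms: [H, HA], pre: [0.070, 0.040], post: [-0.030, 0.060]}
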