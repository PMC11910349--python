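# Default Hounsfield-unit -> mass-density calibration with tissue classes.
# Piecewise-linear in density between anchors; classes partition the HU axis
# (boundaries between classes fall at the midpoint between adjacent anchors
# of different class, boundary HU assigned to the higher-HU class).
# This is a generic stoichiometric-style curve; scanner-specific curves can
# be supplied in the same format.
# Format: hu  density_g_cm3  material
-1000  0.0012  air
-700   0.26    lung
-98    0.93    adipose
14     1.03    soft_tissue
100    1.10    soft_tissue
300    1.35    bone
2000   2.1     bone
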