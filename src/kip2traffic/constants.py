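"""Shared physical and acquisition constants.

The microscopy-derived constants reflect the acquisition setup the tabular
inputs come from: a spinning-disk stack of 17 Z-sections every 1.07 s, a
camera pixel of 133.35 nm, and length bins of two pixels.  The lattice
constants discretize the microtubule at one tubulin dimer (8 nm) per site.
"""

#: Camera pixel size along the scan axis (nm).
PIXEL_SIZE_NM: float = 133.35

#: Time to acquire one full Z-stack; frame interval of the GFP channel (s).
FRAME_INTERVAL_S: float = 1.07

#: Microtubule-length bin width used for profile binning (2 pixels, nm).
BIN_NM: float = 266.7

#: Shortest microtubule considered detectable (5 pixels, nm).
DETECT_LIMIT_NM: float = 666.7

#: Cells with spindles longer than this are excluded from length analysis (µm).
SPINDLE_MAX_UM: float = 2.0

#: Recording window for microtubule-dynamics movies (80 frames x 1.07 s, s).
WINDOW_S: float = 85.6

#: Total-motor-concentration threshold used when conditioning cross-strain
#: likelihood comparisons (nM).
CONDITIONING_NM: float = 35.0

#: Default number of retained likelihood draws for full-scale summaries.
N_DRAWS_DEFAULT: int = 20_000

#: Lattice site length: one tubulin dimer / one kinesin footprint (nm).
SITE_NM: float = 8.0

#: Gaussian PSF sigma for the fluorescence forward model (nm).
PSF_SIGMA_NM: float = 135.0

#: Copies of a solute per nM of concentration in a 1 fL volume.
#: 1 nM * 1 fL = 1e-9 mol/L * 1e-15 L * N_A.
COPIES_PER_NM_FL: float = 6.02214076e23 * 1e-9 * 1e-15

#: Default cytoplasmic volume of a haploid budding-yeast cell (fL).
CELL_VOLUME_FL: float = 40.0
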