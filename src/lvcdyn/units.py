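"""Unit conversions.

All internal quantities are in Hartree atomic units (energy: Hartree,
time: atomic time units, hbar = 1).  Nuclear coordinates are dimensionless
mass-frequency-weighted normal coordinates, so no length unit appears in
the dynamics.  Conversions happen only at I/O boundaries.
"""

# CODATA-2018 derived constants
CM1_TO_HARTREE = 1.0 / 219474.6313632
HARTREE_TO_CM1 = 219474.6313632
EV_TO_HARTREE = 1.0 / 27.211386245988
HARTREE_TO_EV = 27.211386245988
FS_TO_AU = 41.341373335182114  # atomic time units per femtosecond
AU_TO_FS = 1.0 / FS_TO_AU
AMU_TO_ME = 1822.888486209  # electron masses per unified amu


def cm1_to_hartree(x):
    return x * CM1_TO_HARTREE


def hartree_to_cm1(x):
    return x * HARTREE_TO_CM1


def fs_to_au(t):
    return t * FS_TO_AU


def au_to_fs(t):
    return t * AU_TO_FS
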