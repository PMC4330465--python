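"""Packaged reference data.

The acetylcholinesterase (AChE) inhibition training set — 18 sulfonamide/
amide compounds assembled by statistical molecular design and assayed for
half-maximal inhibitory concentration — ships with the package as a small
CSV.  Compound 3 is censored (IC50 reported only as ">1,000" µM because of
poor solubility) and is stored with its published pIC50 of 2.00 and no
IC50 value.

The quantitative physicochemical descriptor matrices of the original study
(325 MOE descriptors over 24 protonation-state records) were published only
as a supplementary spreadsheet and are not redistributed here; analyses
that need quantitative descriptors use :mod:`smdqsar.synthdata`.
"""

from importlib import resources

from .chemio import ActivityTable, read_activity_csv

#: Descriptor names retained for QSAR modelling in the original study:
#: 5 whole-molecule (global) descriptors, 6 for the catalytic-site (CAS)
#: binding moiety and 3 for the peripheral-site (PAS) moiety.
QSAR_DESCRIPTOR_NAMES = [
    "GLOBAL_b_1rotR",
    "GLOBAL_logP_o_w",
    "GLOBAL_TPSA",
    "GLOBAL_vdw_area",
    "GLOBAL_rgyr",
    "CAS_Q_VSA_FPNEG",
    "CAS_Q_VSA_FPPOS",
    "CAS_Q_VSA_FPOS",
    "CAS_AM1_LUMO",
    "CAS_AM1_HOMO",
    "CAS_dipole",
    "PAS_Q_VSA_FPPOS",
    "PAS_AM1_LUMO",
    "PAS_npr1",
]


def load_ache_training_set() -> ActivityTable:
    """The 18-compound AChE training set (IC50 in µM and pIC50)."""
    ref = resources.files("smdqsar.data") / "ache_training_set.csv"
    with resources.as_file(ref) as path:
        return read_activity_csv(path, role="train", set_label="training")
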