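"""Published reference numbers used as worked-example inputs.

These are reported experimental/computational values for the seven
dual-target candidate compounds (CH-1 .. CH-7) and the positive-control
drugs: docking binding free energies against CARM1 and HDAC2, enzyme IC50
values, and the pharmacophore validation confusion counts.  They are
inputs for the arithmetic in this package (threshold cascades, potency
ratios, enrichment statistics) — never fit targets.
"""

from __future__ import annotations

from importlib import resources

from .chem import ScoreRecord, read_score_table

#: Validation-screen confusion counts: database size, actives, hits, active hits.
VALIDATION_COUNTS = {"D": 1500, "A": 16, "Ht": 19, "Ha": 16}

#: Docking-energy cutoffs (kcal/mol) of the dual-target funnel.
CARM1_CUTOFF = -11.3
HDAC2_CUTOFF = -11.7

#: Enzyme IC50 values in nM (mean of replicates).
IC50_NM = {
    "CH-1": {"CARM1": 3.71, "HDAC2": 4.07},
    "CH-2": {"CARM1": 5.38, "HDAC2": 8.33},
    "CH-3": {"CARM1": 10.55, "HDAC2": 5.83},
    "CH-4": {"CARM1": 25.54, "HDAC2": 9.18},
    "CH-5": {"CARM1": 30.14, "HDAC2": 17.27},
    "CH-6": {"CARM1": 37.37, "HDAC2": 12.96},
    "CH-7": {"CARM1": 58.48, "HDAC2": 24.76},
    "EZM2302": {"CARM1": 5.97},
    "vorinostat": {"HDAC2": 9.53},
}


def ch_docking_scores() -> list[ScoreRecord]:
    """The packaged CH-1..CH-7 docking score table (14 records, kcal/mol)."""
    ref = resources.files("dualphore.data").joinpath("docking_scores_chs.csv")
    with resources.as_file(ref) as path:
        return read_score_table(path)
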