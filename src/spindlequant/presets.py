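"""Reference turnover-parameter sets for GFP-Dgt2 FRAP by condition.

Each entry holds the fitted recovery parameters reported for spindle-
associated GFP-Dgt2 (an Augmin subunit) in a given genotype/cell type, and
is used by the synthetic generator as a ground-truth forward model:

* ``oocyte_metaphase_I`` — wild-type metaphase I oocytes: two turnover
  populations, 85% slow (t1/2 = 5 min) and 15% fast (t1/2 = 8 s).
* ``syncytial_embryo`` — wild-type syncytial-embryo mitosis: one turnover
  population of 85% (t1/2 = 15 s) plus a 15% immobile remainder.
* ``gamma_tubulin_rnai`` — oocytes depleted of gamma-tubulin37C by RNAi:
  the slow population drops to 74% and speeds up to t1/2 = 170 s
  (2 min 50 s); the fast population keeps t1/2 = 8 s.
* ``ncd_mutant`` — kinesin-14 ncd mutant oocytes: 82% slow with
  t1/2 = 190 s (3 min 10 s); fast population unchanged.
"""

from __future__ import annotations

from .frap import RecoveryParams

__all__ = ["CONDITIONS", "CONDITION_N_TRACES"]

CONDITIONS: dict[str, RecoveryParams] = {
    "oocyte_metaphase_I": RecoveryParams(
        "two_population", f=0.15, s=0.85, tf_half=8.0, ts_half=300.0
    ),
    "syncytial_embryo": RecoveryParams(
        "single_plus_immobile", f=0.85, tf_half=15.0
    ),
    "gamma_tubulin_rnai": RecoveryParams(
        "two_population", f=0.26, s=0.74, tf_half=8.0, ts_half=170.0
    ),
    "ncd_mutant": RecoveryParams(
        "two_population", f=0.18, s=0.82, tf_half=8.0, ts_half=190.0
    ),
}

#: Number of spindles pooled per condition (n >= 15 in meiosis,
#: n >= 11 in syncytial mitosis).
CONDITION_N_TRACES: dict[str, int] = {
    "oocyte_metaphase_I": 15,
    "syncytial_embryo": 11,
    "gamma_tubulin_rnai": 15,
    "ncd_mutant": 15,
}
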