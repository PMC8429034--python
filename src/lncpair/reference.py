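"""Published reference values from the TCGA-KIRC lncRNA-pair signature.

The packaged tables carry the 12-pair prognostic signature reported for
the TCGA kidney clear cell renal cell carcinoma cohort (coefficients,
hazard ratios, Wald confidence bounds, p-values) and the cohort's
clinicopathological counts by risk group (530 patients: 220 high risk,
310 low risk).  They serve as fixtures for analytic identity checks
(``exp(coef) == HR``, CI geometric-mean identity, percentage arithmetic)
and as a worked example of the signature's output schema.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

_DATA = files("lncpair") / "data"


def load_reference_signature() -> pd.DataFrame:
    """The 12 retained lncRNA pairs with multivariable Cox statistics."""
    return pd.read_csv(str(_DATA / "kirc_signature.tsv"), sep="\t")


def load_reference_clinical_counts() -> pd.DataFrame:
    """Per-level patient counts (and printed percentages) by risk group."""
    return pd.read_csv(str(_DATA / "kirc_clinical_counts.tsv"), sep="\t")


REFERENCE_GROUP_SIZES = {"overall": 530, "high": 220, "low": 310}
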