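"""Synthetic tumor/normal cohorts with a planted pair-based hazard.

The generator reproduces the statistical structure the pipeline assumes:

* immune genes with unit-variance log-expression; a subset of lncRNAs is
  coupled to one immune gene each (``lnc = gene + noise``), so the
  population Pearson correlation is ``1/sqrt(1 + noise_sd^2)``;
* a subset of the coupled lncRNAs is differentially expressed between
  tumor and normal samples with a planted log2 fold change (the shift is
  applied to the carrier immune gene, so coupling survives the shift);
* overall survival of tumor samples follows an exponential
  proportional-hazards model whose linear predictor is a weighted sum of
  planted within-sample rank-pair indicators, with independent
  exponential censoring;
* grade/stage/TNM are drawn with probabilities shifted upward in the top
  tertile of the linear predictor, and immune-infiltration fractions,
  checkpoint expression and an IC50-like drug score are mixed with the
  linear predictor through a single mixing weight.

Times are in days.  Normal samples appear in the clinical table with all
survival and staging fields missing; only tumor samples enter survival
modelling.  Negative-binomial count noise, batch effects and tumor
purity are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, NORMAL, TUMOR, write_clinical, write_table

CHECKPOINT_GENES = ("PDCD1", "CD247", "CTLA4", "TIGIT", "LAG3")

NOISE_CELL_TYPES = (
    "CD8_T", "CD4_T", "NK", "B_cell", "Macrophage_M1",
    "Macrophage_M2", "Neutrophil", "Dendritic",
)


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of the emulated study cohort.

    Defaults mirror a mid-size tumor/normal profiling cohort with a
    strong planted three-pair hazard: 300 tumor and 50 normal samples,
    200 lncRNAs of which 40 are immune-coupled and 20 differentially
    expressed at |log2FC| = 2, pair log-hazard coefficients of
    magnitude >= 0.8, and exponential event/censoring rates giving
    roughly 60% observed events.
    """

    n_tumor: int = 300
    n_normal: int = 50
    n_lnc: int = 200
    n_irgene: int = 100
    n_linked: int = 40
    n_de: int = 20
    de_log2fc: float = 2.0
    n_true_pairs: int = 3
    pair_coefs: tuple[float, ...] = (1.0, -0.9, 0.8)
    baseline_hazard: float = 0.0009   # events per day at linear predictor 0
    censor_rate: float = 0.0006      # censorings per day
    noise_sd: float = 0.3            # residual sd of coupled log-expression
    de_up_fraction: float = 0.85     # fraction of DE lncRNAs shifted upward
    assoc_mixing: float = 0.6        # weight tying annotations to the risk
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_tumor=self.n_tumor, n_normal=self.n_normal,
                      n_lnc=self.n_lnc, n_irgene=self.n_irgene,
                      n_linked=self.n_linked, n_de=self.n_de)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (self.n_de <= self.n_linked <= self.n_lnc):
            raise ValueError("require n_de <= n_linked <= n_lnc")
        if self.n_linked > self.n_irgene:
            raise ValueError("n_linked exceeds n_irgene")
        if self.n_true_pairs > self.n_de * (self.n_de - 1) // 2:
            raise ValueError("n_true_pairs exceeds n_de*(n_de-1)/2")
        if len(self.pair_coefs) != self.n_true_pairs:
            raise ValueError("pair_coefs length must equal n_true_pairs")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 <= self.assoc_mixing <= 1:
            raise ValueError("assoc_mixing must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Bundled synthetic tables plus the planted ground truth."""

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    infiltration: pd.DataFrame        # cell type x tumor sample, in [0,1]
    checkpoints: pd.DataFrame         # checkpoint gene x tumor sample
    drug_scores: pd.Series            # IC50-like, lower = more sensitive
    truth: pd.DataFrame               # pair_id, lnc_a, lnc_b, coef
    de_ids: list[str]                 # planted DE lncRNA identifiers
    annotation: pd.Series             # feature -> biotype
    immune_genes: list[str]
    params: SimulationParams


# --- naming helpers --------------------------------------------------------

def _lnc_ids(n: int) -> list[str]:
    return [f"LNC{i + 1:04d}" for i in range(n)]


def _irg_ids(n: int) -> list[str]:
    return [f"IRG{i + 1:04d}" for i in range(n)]


def _sample_ids(params: SimulationParams) -> tuple[list[str], list[str]]:
    tum = [f"TUM{i + 1:04d}" for i in range(params.n_tumor)]
    nor = [f"NOR{i + 1:04d}" for i in range(params.n_normal)]
    return tum, nor


def _de_signs(params: SimulationParams) -> np.ndarray:
    """Planted DE direction per DE lncRNA: up first, then down."""
    n_up = max(1, int(round(params.de_up_fraction * params.n_de)))
    n_up = min(n_up, params.n_de)
    return np.concatenate([np.ones(n_up), -np.ones(params.n_de - n_up)])


def planted_pairs(params: SimulationParams) -> pd.DataFrame:
    """Deterministically choose the planted pairs among up-shifted DE lncRNAs.

    Pairs are drawn among lncRNAs with the same planted shift so their
    rank indicator stays balanced (ones fraction near 0.5) and survives
    the stability filter.  Pair ids are canonical (lexicographic A|B);
    the stored coefficient applies to the canonical indicator 1[A > B].
    """
    rng = np.random.default_rng(params.seed + 101)
    signs = _de_signs(params)
    lnc = np.array(_lnc_ids(params.n_lnc))
    de = lnc[: params.n_de]
    up = de[signs > 0]
    candidates = [(a, b) for i, a in enumerate(up) for b in up[i + 1:]]
    if len(candidates) < params.n_true_pairs:
        raise ValueError("not enough up-shifted DE lncRNAs to plant pairs")
    idx = rng.choice(len(candidates), size=params.n_true_pairs, replace=False)
    rows = []
    for k, i in enumerate(sorted(idx)):
        a, b = candidates[i]
        rows.append({"pair_id": f"{a}|{b}", "lnc_a": a, "lnc_b": b,
                     "coef": float(params.pair_coefs[k])})
    return pd.DataFrame(rows)


# --- expression ------------------------------------------------------------

def generate_expression(params: SimulationParams) -> ExpressionMatrix:
    """Emit the (n_lnc + n_irgene) x (n_tumor + n_normal) log-expression matrix.

    Coupled lncRNA j equals immune gene j plus N(0, noise_sd) noise; DE
    lncRNAs are the first ``n_de`` coupled ones, their carrier immune
    gene shifted by ±``de_log2fc`` in tumor samples.
    """
    rng = np.random.default_rng(params.seed)
    tum, nor = _sample_ids(params)
    samples = tum + nor
    n = len(samples)
    is_tumor = np.array([1.0] * params.n_tumor + [0.0] * params.n_normal)

    mu_g = rng.uniform(4.0, 8.0, size=params.n_irgene)
    # DE carrier genes form a co-regulated module with a shared baseline
    # mean, so rank pairs among their coupled lncRNAs stay balanced
    mu_g[: params.n_de] = 6.0
    genes = mu_g[:, None] + rng.normal(size=(params.n_irgene, n))
    signs = _de_signs(params)
    for j in range(params.n_de):
        genes[j] += signs[j] * params.de_log2fc * is_tumor

    lnc = np.empty((params.n_lnc, n))
    lnc[: params.n_linked] = (
        genes[: params.n_linked]
        + rng.normal(scale=params.noise_sd, size=(params.n_linked, n))
    )
    n_free = params.n_lnc - params.n_linked
    mu_l = rng.uniform(2.0, 6.0, size=n_free)
    lnc[params.n_linked:] = mu_l[:, None] + rng.normal(size=(n_free, n))

    values = pd.DataFrame(
        np.vstack([lnc, genes]),
        index=_lnc_ids(params.n_lnc) + _irg_ids(params.n_irgene),
        columns=samples,
    )
    group = pd.Series([TUMOR] * params.n_tumor + [NORMAL] * params.n_normal,
                      index=samples, name="group")
    return ExpressionMatrix(values=values, group=group)


# --- survival --------------------------------------------------------------

# category probabilities for the bulk of the cohort vs the top risk
# tertile, chosen to reproduce the grade/stage/TNM contrast a high- vs
# low-risk split shows in published ccRCC risk-model cohorts
GRADE_BASE = (0.04, 0.55, 0.33, 0.08)
GRADE_TOP = (0.01, 0.24, 0.45, 0.30)
STAGE_BASE = (0.60, 0.11, 0.20, 0.09)
STAGE_TOP = (0.30, 0.11, 0.32, 0.27)
T_BASE = (0.58, 0.15, 0.25, 0.02)
T_TOP = (0.32, 0.12, 0.49, 0.07)
N_BASE = (0.45, 0.015, 0.535)
N_TOP = (0.42, 0.06, 0.52)
M_BASE = (0.86, 0.08, 0.06)
M_TOP = (0.68, 0.27, 0.05)


def pair_indicator(expression: ExpressionMatrix, lnc_a: str, lnc_b: str,
                   samples: list[str]) -> np.ndarray:
    a = expression.values.loc[lnc_a, samples].to_numpy()
    b = expression.values.loc[lnc_b, samples].to_numpy()
    return (a > b).astype(float)


def generate_survival(expression: ExpressionMatrix,
                      params: SimulationParams) -> pd.DataFrame:
    """Draw survival and clinical covariates for the cohort.

    Tumor event times are exponential with hazard
    ``baseline_hazard * exp(sum_i coef_i * value_i)`` where ``value_i``
    is the planted pair indicator; censoring is independent exponential
    at ``censor_rate``.  Grade/stage/TNM are drawn with elevated
    probabilities in the top tertile of the linear predictor.  Normal
    samples get missing survival/staging fields.
    """
    truth = planted_pairs(params)
    missing = [f for f in pd.unique(truth[["lnc_a", "lnc_b"]].values.ravel())
               if f not in expression.values.index]
    if missing:
        raise ValueError(f"planted pairs reference absent lncRNAs: {missing}")

    rng = np.random.default_rng(params.seed + 1)
    tum = expression.tumor_samples
    nor = expression.normal_samples
    nt = len(tum)

    lp = np.zeros(nt)
    for _, row in truth.iterrows():
        lp += row["coef"] * pair_indicator(expression, row["lnc_a"],
                                           row["lnc_b"], tum)

    hazard = params.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if params.censor_rate > 0:
        t_cens = rng.exponential(1.0 / params.censor_rate, size=nt)
    else:
        t_cens = np.full(nt, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    age = np.clip(np.round(rng.normal(60.5, 12.0, size=nt)), 30, 90)
    gender = rng.choice(["female", "male"], size=nt, p=[0.35, 0.65])

    top = lp >= np.quantile(lp, 2.0 / 3.0)

    def _draw(levels, base, shifted):
        out = np.empty(nt, dtype=object)
        out[~top] = rng.choice(levels, size=int((~top).sum()), p=base)
        out[top] = rng.choice(levels, size=int(top.sum()), p=shifted)
        return out

    grade = _draw(["G1", "G2", "G3", "G4"], GRADE_BASE, GRADE_TOP)
    stage = _draw(["I", "II", "III", "IV"], STAGE_BASE, STAGE_TOP)
    t_stage = _draw(["T1", "T2", "T3", "T4"], T_BASE, T_TOP)
    n_stage = _draw(["N0", "N1", "NX"], N_BASE, N_TOP)
    m_stage = _draw(["M0", "M1", "MX"], M_BASE, M_TOP)

    tumor_df = pd.DataFrame({
        "os_time": os_time, "os_event": os_event, "age": age,
        "gender": gender, "grade": grade, "stage": stage,
        "t_stage": t_stage, "n_stage": n_stage, "m_stage": m_stage,
        "linear_predictor": lp,
    }, index=pd.Index(tum, name="sample_id"))
    normal_df = pd.DataFrame(
        {c: np.nan for c in tumor_df.columns},
        index=pd.Index(nor, name="sample_id"),
    )
    return pd.concat([tumor_df, normal_df])


# --- annotations (infiltration, checkpoints, drug) -------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_annotations(clinical: pd.DataFrame, params: SimulationParams,
                         seed: int | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Infiltration fractions, checkpoint expression and drug scores.

    A single mixing weight ``w = assoc_mixing`` controls how tightly each
    annotation tracks the survival linear predictor: the Tregs fraction
    and the five checkpoint genes increase with it, the IC50-like drug
    score decreases with it.  ``w = 1`` makes them deterministic monotone
    transforms of the linear predictor; ``w = 0`` makes them independent
    noise.
    """
    if "linear_predictor" not in clinical.columns:
        raise ValueError("clinical table lacks the linear_predictor column")
    tum = clinical.index[clinical["linear_predictor"].notna()]
    lp = clinical.loc[tum, "linear_predictor"].to_numpy(dtype=float)
    sd = lp.std()
    z = (lp - lp.mean()) / sd if sd > 0 else np.zeros_like(lp)
    rng = np.random.default_rng((params.seed if seed is None else seed) + 2)
    w = params.assoc_mixing
    nt = len(tum)

    def mix(sign: float) -> np.ndarray:
        return sign * w * z + (1.0 - w) * rng.normal(size=nt)

    rows = {"Tregs": 0.05 + 0.25 * _sigmoid(mix(+1.0))}
    for ct in NOISE_CELL_TYPES:
        rows[ct] = 0.05 + 0.25 * _sigmoid(rng.normal(size=nt))
    infiltration = pd.DataFrame(rows, index=tum).T
    infiltration.index.name = "cell_type"

    checkpoints = pd.DataFrame(
        {g: 4.0 + mix(+1.0) for g in CHECKPOINT_GENES}, index=tum
    ).T
    checkpoints.index.name = "gene"

    drug = pd.Series(3.0 + mix(-1.0), index=tum, name="sunitinib_ic50")
    return infiltration, checkpoints, drug


# --- orchestration ---------------------------------------------------------

def generate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Generate the full cohort; identical params give identical output."""
    expression = generate_expression(params)
    clinical = generate_survival(expression, params)
    infiltration, checkpoints, drug = generate_annotations(clinical, params)
    truth = planted_pairs(params)
    annotation = pd.Series(
        {f: ("lncRNA" if f.startswith("LNC") else "protein_coding")
         for f in expression.feature_ids},
        name="biotype",
    )
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        infiltration=infiltration,
        checkpoints=checkpoints,
        drug_scores=drug,
        truth=truth,
        de_ids=_lnc_ids(params.n_lnc)[: params.n_de],
        annotation=annotation,
        immune_genes=_irg_ids(params.n_irgene),
        params=params,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort in the TSV dialects the io module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.write(outdir / "expression.tsv", outdir / "groups.tsv")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    write_table(cohort.infiltration, outdir / "infiltration.tsv", "cell_type")
    write_table(cohort.checkpoints, outdir / "checkpoints.tsv", "gene")
    cohort.drug_scores.rename("sunitinib_ic50").to_frame().rename_axis(
        "sample_id").to_csv(outdir / "drug_scores.tsv", sep="\t")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.annotation.rename("biotype").to_frame().rename_axis(
        "feature_id").to_csv(outdir / "annotation.tsv", sep="\t")
    (outdir / "immune_genes.txt").write_text(
        "\n".join(cohort.immune_genes) + "\n")


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    return replace(params, seed=seed)
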