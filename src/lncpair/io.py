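"""Input/output and the shared data model.

All tables are plain TSV (tab-separated, UTF-8, header row).  Expression
matrices are features x samples with the feature identifier in the first
column; sample group labels (tumor/normal) live in a separate two-column
table.  Gene biotypes come either from a two-column TSV or from a minimal
GTF whose gene features carry ``gene_id``/``gene_name`` and
``gene_biotype``/``gene_type`` attributes.

Expression values are assumed already log-transformed and normalized;
``read_expression(..., log2p1=True)`` applies log2(x+1) for raw inputs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("lncpair")

TUMOR = "tumor"
NORMAL = "normal"

#: clinical categorical levels treated as unknown/not-assessable and kept
#: out of contingency tests
UNKNOWN_LEVELS = {"GX", "NX", "MX", "TX", "Unknown", "unknown", "NA", ""}

CLINICAL_REQUIRED = ("os_time", "os_event")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, features x samples, with tumor/normal labels."""

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dup)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        self.group = self.group.loc[self.values.columns]
        bad = set(self.group.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.group.index[self.group == TUMOR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.group.index[self.group == NORMAL])

    def subset(self, features: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        v = self.values
        if features is not None:
            v = v.loc[[f for f in features if f in v.index]]
        if samples is not None:
            v = v[[s for s in samples if s in v.columns]]
        return ExpressionMatrix(values=v.copy(), group=self.group.loc[v.columns].copy())

    def write(self, expr_path: str | Path, group_path: str | Path | None = None) -> None:
        df = self.values.copy()
        df.index.name = "feature_id"
        df.to_csv(expr_path, sep="\t")
        if group_path is not None:
            g = self.group.rename("group").to_frame()
            g.index.name = "sample_id"
            g.to_csv(group_path, sep="\t")


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_expression(path: str | Path, group_map: Mapping[str, str],
                    log2p1: bool = False) -> ExpressionMatrix:
    """Read a features x samples TSV and attach tumor/normal labels.

    Duplicate feature rows are collapsed by their mean (logged).  A
    non-numeric cell raises with the offending row/column coordinates; a
    header sample missing from ``group_map`` raises naming the sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if num.index.duplicated().any():
        n_dup = int(num.index.duplicated().sum())
        logger.info("collapsing %d duplicate feature rows by mean", n_dup)
        num = num.groupby(level=0, sort=False).mean()
    missing = [s for s in num.columns if s not in group_map]
    if missing:
        raise ValueError(f"samples absent from group map: {missing}")
    if log2p1:
        num = np.log2(num + 1.0)
    group = pd.Series({s: group_map[s] for s in num.columns}, name="group")
    return ExpressionMatrix(values=num.astype(float), group=group)


# ---------------------------------------------------------------------------
# clinical table

def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample clinical table (index = sample id)."""
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    t = df["os_time"].dropna()
    if (t < 0).any():
        raise ValueError("os_time must be non-negative")
    e = df["os_event"].dropna()
    if not set(np.unique(e)) <= {0, 1, 0.0, 1.0}:
        raise ValueError("os_event must be 0/1")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def survival_cohort(clinical: pd.DataFrame) -> pd.DataFrame:
    """Samples with usable overall-survival data (the modelling cohort)."""
    ok = clinical["os_time"].notna() & clinical["os_event"].notna()
    ok &= clinical["os_time"] > 0
    return clinical.loc[ok]


# ---------------------------------------------------------------------------
# gene annotation

LEGACY_LNC_BIOTYPES = {"lincRNA", "antisense", "processed_transcript"}

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def extract_biotypes(gtf_path: str | Path, legacy_lnc: bool = False,
                     id_attr: str = "gene_name") -> pd.Series:
    """Map gene id -> biotype in {protein_coding, lncRNA, other} from a GTF.

    Only ``gene`` features are considered; comment lines are skipped.
    Records missing the id or biotype attribute are skipped with a warning.
    With ``legacy_lnc`` the older Ensembl biotypes (lincRNA, antisense,
    processed_transcript) fold into lncRNA; the default is the strict
    current "lncRNA" label.
    """
    mapping: dict[str, str] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            gid = attrs.get(id_attr) or attrs.get("gene_id")
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type")
            if gid is None or biotype is None:
                logger.warning("skipping gene record without %s/biotype", id_attr)
                continue
            if biotype == "lncRNA" or (legacy_lnc and biotype in LEGACY_LNC_BIOTYPES):
                mapping[gid] = "lncRNA"
            elif biotype == "protein_coding":
                mapping[gid] = "protein_coding"
            else:
                mapping[gid] = "other"
    return pd.Series(mapping, name="biotype")


def read_biotype_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    s = pd.Series(df.iloc[:, 1].str.strip().values,
                  index=df.iloc[:, 0].str.strip(), name="biotype")
    return s


def read_immune_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def split_by_biotype(expr: ExpressionMatrix, annotation: pd.Series,
                     immune_list: Iterable[str]) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split into (lncRNA rows, immune protein-coding rows), order preserved."""
    immune = set(immune_list)
    ann = annotation.reindex(expr.feature_ids)
    lnc_ids = [f for f, b in ann.items() if b == "lncRNA"]
    ir_ids = [f for f, b in ann.items() if b == "protein_coding" and f in immune]
    if not ir_ids:
        raise ValueError(
            "no protein-coding feature intersects the immune-gene list; "
            "check that expression, annotation and immune list share the "
            "same identifier space (symbols vs Ensembl ids)"
        )
    return expr.subset(features=lnc_ids), expr.subset(features=ir_ids)


# ---------------------------------------------------------------------------
# generic helpers

def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index_name: str | None = None) -> None:
    out = df.copy()
    if index_name is not None:
        out.index.name = index_name
    out.to_csv(path, sep="\t")
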