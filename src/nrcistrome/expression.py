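"""Differential expression over a 2x2 genotype-by-treatment design and the
eight-way response-type classification.

The design crosses genotype (``wt`` = receptor wild-type, ``null`` =
receptor knockout) with treatment (``vehicle``, ``ligand``), with
replicates.  Three contrasts characterize each gene:

* ``genotype``    — null+vehicle vs wt+vehicle (constitutive receptor effect)
* ``ligand_wt``   — wt+ligand vs wt+vehicle (ligand effect in wild-type)
* ``ligand_null`` — null+ligand vs null+vehicle (ligand effect without receptor)

A gene is significant in a contrast when its BH-adjusted q-value and fold
change clear the thresholds (defaults: fold change 1.3, FDR 0.25).  The
constitutive call reads the genotype contrast: knockout-up means the
receptor *represses* the gene, knockout-down means it *activates* it.  The
ligand call reads ``ligand_wt`` but is only receptor-dependent when the
same contrast is not significant in knockout cells; a ligand response that
persists without the receptor voids the classification (type ``none``,
flagged ``ligand_independent``).  The two calls map onto response types:

=============  ==========  ====
constitutive   ligand      type
=============  ==========  ====
repressed      --          I
activated      --          II
--             activated   III
--             repressed   IV
repressed      activated   V
activated      repressed   VI
activated      activated   VII
repressed      repressed   VIII
=============  ==========  ====
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "genotype": (("null", "vehicle"), ("wt", "vehicle")),
    "ligand_wt": (("wt", "ligand"), ("wt", "vehicle")),
    "ligand_null": (("null", "ligand"), ("null", "vehicle")),
}

RESPONSE_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

_TYPE_MAP: dict[tuple[str, str], str] = {
    ("repressed", "none"): "I",
    ("activated", "none"): "II",
    ("none", "activated"): "III",
    ("none", "repressed"): "IV",
    ("repressed", "activated"): "V",
    ("activated", "repressed"): "VI",
    ("activated", "activated"): "VII",
    ("repressed", "repressed"): "VIII",
    ("none", "none"): "none",
}


@dataclass(frozen=True)
class ClassifierThresholds:
    fc_min: float = 1.3
    fdr_max: float = 0.25

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")


@dataclass
class ExpressionMatrix:
    """log2 expression values (genes x samples) plus a sample sheet.

    ``design`` must have columns ``sample``, ``genotype`` (wt/null),
    ``treatment`` (vehicle/ligand) and ``replicate``; every
    genotype-treatment condition needs at least two replicates.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "genotype", "treatment", "replicate"}
        missing = required - set(self.design.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        unknown = set(self.design["sample"]) - set(self.values.columns)
        if unknown:
            raise ValueError(f"samples absent from matrix: {sorted(unknown)}")
        if self.values[self.design["sample"]].isna().any().any():
            raise ValueError("expression matrix contains missing values")
        sizes = self.design.groupby(["genotype", "treatment"]).size()
        if (sizes < 2).any():
            raise ValueError("every condition needs at least 2 replicates")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def condition_samples(self, genotype: str, treatment: str) -> list[str]:
        mask = (self.design["genotype"] == genotype) & (
            self.design["treatment"] == treatment
        )
        samples = list(self.design.loc[mask, "sample"])
        if not samples:
            raise ValueError(f"no samples for condition ({genotype}, {treatment})")
        return samples

    def condition_values(self, genotype: str, treatment: str) -> np.ndarray:
        return self.values[self.condition_samples(genotype, treatment)].to_numpy()

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, design_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        # keep_default_na: the genotype label "null" must survive as a string
        design = pd.read_csv(design_path, sep="\t", keep_default_na=False)
        return cls(values, design)

    def to_tsv(self, matrix_path: str | Path, design_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.design.to_csv(design_path, sep="\t", index=False)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_stats(
    matrix: ExpressionMatrix,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    label: str = "",
) -> pd.DataFrame:
    """Per-gene Welch t contrast of condition ``group_a`` vs ``group_b``.

    Returns a DataFrame indexed by gene with columns ``delta`` (mean log2
    difference A-B), ``fold_change`` (>= 1), ``direction`` (up/down), ``p``
    and BH ``q``.  Genes with zero variance in both groups get p = 1 when
    the means agree and p = 0 (with a warning) otherwise.
    """
    a = matrix.condition_values(*group_a)
    b = matrix.condition_values(*group_b)
    delta = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        p = np.array(p, copy=True)
        zero_delta = np.isclose(delta, 0)
        p[degenerate & zero_delta] = 1.0
        if (degenerate & ~zero_delta).any():
            warnings.warn(
                "zero within-group variance with nonzero difference; p set to 0",
                stacklevel=2,
            )
        p[degenerate & ~zero_delta] = 0.0
    out = pd.DataFrame(
        {
            "contrast": label or f"{group_a[0]}_{group_a[1]}_vs_{group_b[0]}_{group_b[1]}",
            "delta": delta,
            "fold_change": np.power(2.0, np.abs(delta)),
            "direction": np.where(delta > 0, "up", "down"),
            "p": p,
            "q": bh_adjust(p),
        },
        index=matrix.values.index,
    )
    return out


def _significant(contrast: pd.DataFrame, thr: ClassifierThresholds) -> pd.Series:
    return (contrast["fold_change"] >= thr.fc_min) & (contrast["q"] <= thr.fdr_max)


def classify_gene(
    ligand_wt: Mapping[str, float],
    genotype: Mapping[str, float],
    ligand_null: Mapping[str, float],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> dict:
    """Classify one gene from its three contrast rows.

    Each argument is a mapping with keys ``fold_change``, ``direction`` and
    ``q`` (one row of a :func:`contrast_stats` frame).
    """
    for name, row in (("ligand_wt", ligand_wt), ("genotype", genotype), ("ligand_null", ligand_null)):
        if row is None:
            raise ValueError(f"missing contrast: {name}")

    def sig(row: Mapping[str, float]) -> bool:
        return row["fold_change"] >= thresholds.fc_min and row["q"] <= thresholds.fdr_max

    constitutive = "none"
    if sig(genotype):
        constitutive = "repressed" if genotype["direction"] == "up" else "activated"
    ligand_independent = sig(ligand_wt) and sig(ligand_null)
    ligand = "none"
    if sig(ligand_wt) and not sig(ligand_null):
        ligand = "activated" if ligand_wt["direction"] == "up" else "repressed"
    if ligand_independent:
        response_type = "none"
    else:
        response_type = _TYPE_MAP[(constitutive, ligand)]
    return {
        "constitutive": constitutive,
        "ligand": ligand,
        "response_type": response_type,
        "ligand_independent": ligand_independent,
    }


def classify_all(
    matrix: ExpressionMatrix,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the three contrasts and classify every gene.

    Returns ``(table, counts)`` where ``table`` is indexed by gene with the
    per-contrast statistics, the two calls and the response type, and
    ``counts`` maps each response type (I..VIII) to its gene count.  The
    table also carries ``lig_over_geno_ratio``, the linear-scale ratio of
    the ligand response over the constitutive response used to summarize
    switch-type (V/VI) genes.
    """
    frames = {
        name: contrast_stats(matrix, a, b, label=name)
        for name, (a, b) in CONTRASTS.items()
    }
    table = pd.DataFrame(index=matrix.values.index)
    for name, frame in frames.items():
        for col in ("delta", "fold_change", "direction", "p", "q"):
            table[f"{name}_{col}"] = frame[col]

    sig = {name: _significant(frames[name], thresholds) for name in frames}
    constitutive = np.where(
        sig["genotype"],
        np.where(frames["genotype"]["direction"] == "up", "repressed", "activated"),
        "none",
    )
    ligand_independent = (sig["ligand_wt"] & sig["ligand_null"]).to_numpy()
    ligand = np.where(
        sig["ligand_wt"] & ~sig["ligand_null"],
        np.where(frames["ligand_wt"]["direction"] == "up", "activated", "repressed"),
        "none",
    )
    response = np.array(
        [_TYPE_MAP[(c, l)] for c, l in zip(constitutive, ligand)], dtype=object
    )
    response[ligand_independent] = "none"
    table["constitutive"] = constitutive
    table["ligand"] = ligand
    table["ligand_independent"] = ligand_independent
    table["response_type"] = response
    # linear ratio of (wt+ligand vs wt+vehicle) over (null vs wt vehicle)
    table["lig_over_geno_ratio"] = np.power(
        2.0, table["ligand_wt_delta"] - table["genotype_delta"]
    )
    counts = {t: int((response == t).sum()) for t in RESPONSE_TYPES}
    return table, counts


def switch_ratio_summary(table: pd.DataFrame) -> dict[str, float]:
    """Mean ligand-over-constitutive expression ratio for switch types V/VI."""
    out = {}
    for t in ("V", "VI"):
        mask = table["response_type"] == t
        out[t] = float(table.loc[mask, "lig_over_geno_ratio"].mean()) if mask.any() else float("nan")
    return out


def response_type_proportions(counts: Mapping[str, int]) -> dict[str, float]:
    """Summary proportions over per-type gene counts.

    ``major_pct`` covers the four single-mechanism types I-IV; ``mixed_pct``
    the combined types V-VIII; ``constitutive_total`` (types I+II) counts
    genes regulated without exogenous ligand and ``ligand_total`` (III+IV)
    genes requiring the ligand.  Percentages are of the classified total.
    """
    missing = [t for t in RESPONSE_TYPES if t not in counts]
    if missing:
        raise ValueError(f"missing response-type counts: {missing}")
    total = sum(int(counts[t]) for t in RESPONSE_TYPES)
    if total == 0:
        raise ValueError("no classified genes")
    major = sum(int(counts[t]) for t in ("I", "II", "III", "IV"))
    mixed = total - major
    constitutive_total = int(counts["I"]) + int(counts["II"])
    ligand_total = int(counts["III"]) + int(counts["IV"])
    return {
        "total": float(total),
        "major_pct": 100.0 * major / total,
        "mixed_pct": 100.0 * mixed / total,
        "constitutive_total": float(constitutive_total),
        "ligand_total": float(ligand_total),
        "constitutive_pct": 100.0 * constitutive_total / total,
        "ligand_pct": 100.0 * ligand_total / total,
    }
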