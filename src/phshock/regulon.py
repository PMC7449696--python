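"""Regulon-level pH-sensitivity scoring of bulk expression tables.

Input is a genes x samples table of transcripts per million (tpm) with a
sample sheet recording, per column, the temperature treatment (heat shock vs
mock), whether intracellular acidification was allowed or prevented (media
pH), the translation state, and the replicate.  Per gene, two ratios are
computed after averaging replicates within condition:

* induction fold change — shocked vs mock abundance;
* acidification fold change — abundance after shock *with* acidification vs
  after shock with acidification prevented, within one translation state.

Gene sets (regulons of individual transcription factors, read from GMT
files) are then summarized: mean log2 induction, median acidification fold
change, and a rank-sum test of the regulon's acidification ratios against
background genes.  Two rules mirror the curation of the source regulons:
regulons with fewer than 4 genes are dropped, and genes belonging to the
Hsf1 or Msn2/4 regulons are excluded from every other regulon (and from the
background), so the canonical heat-shock sets cannot leak signal into
bystander sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .subpop import compare_class_ph

__all__ = [
    "RegulonSet",
    "RegulonScore",
    "read_gmt",
    "write_gmt",
    "combine_replicates",
    "induction_fold_change",
    "acidification_fold_change",
    "exclude_core_regulon_genes",
    "score_regulons",
    "test_regulon_vs_background",
]

MIN_REGULON_SIZE = 4
CORE_REGULONS = ("Hsf1", "Msn2/4")
DEFAULT_PSEUDOCOUNT = 1.0  # tpm


@dataclass
class RegulonSet:
    """One transcription factor's target-gene set."""

    tf: str
    genes: tuple[str, ...]
    annotation: str = "heat-shock-annotated"  # or "non-stress-annotated"

    def __post_init__(self) -> None:
        self.genes = tuple(dict.fromkeys(self.genes))  # dedupe, keep order


@dataclass
class RegulonScore:
    tf: str
    n_genes: int
    mean_log2_induction: float
    median_acid_fold: float
    p_vs_background: float
    ecdf_x: np.ndarray = field(repr=False, default=None)
    ecdf_y: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# GMT gene sets (name <tab> description <tab> gene1 <tab> gene2 ...)

def read_gmt(path) -> list[RegulonSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >= 3 tab fields): {line[:80]!r}")
            name, desc = fields[0], fields[1]
            sets.append(RegulonSet(tf=name, genes=tuple(g for g in fields[2:] if g),
                                   annotation=desc or "heat-shock-annotated"))
    if not sets:
        raise ValueError(f"empty gene-set file: {path}")
    return sets


def write_gmt(sets: list[RegulonSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.tf, s.annotation, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# tpm-table arithmetic

def combine_replicates(tpm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns, returning one column per condition.

    ``samples`` must have columns ``sample`` (matching tpm columns),
    ``temperature``, ``acidification``, ``translation``; the output columns
    are "temperature|acidification|translation" keys.
    """
    required = {"sample", "temperature", "acidification", "translation"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    out = {}
    for key, group in samples.groupby(["temperature", "acidification", "translation"]):
        cols = [s for s in group["sample"] if s in tpm.columns]
        if not cols:
            raise ValueError(f"condition {key} has no matching tpm columns")
        out["|".join(key)] = tpm[cols].mean(axis=1)
    return pd.DataFrame(out, index=tpm.index)


def _condition_key(temperature: str, acidification: str, translation: str) -> str:
    return f"{temperature}|{acidification}|{translation}"


def _ratio(cond: pd.DataFrame, num_key: str, den_key: str, pseudo: float) -> pd.Series:
    for key in (num_key, den_key):
        if key not in cond.columns:
            raise ValueError(f"condition {key!r} absent from matrix "
                             f"(have {sorted(cond.columns)})")
    return (cond[num_key] + pseudo) / (cond[den_key] + pseudo)


def induction_fold_change(
    cond: pd.DataFrame,
    acidification: str = "allowed",
    translation: str = "active",
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene (shock + pseudo) / (mock + pseudo) within one arm.

    The 1-tpm default pseudocount stabilizes ratios of low-abundance genes;
    pass 0 for exact arithmetic on toy tables.
    """
    return _ratio(
        cond,
        _condition_key("shock", acidification, translation),
        _condition_key("mock", acidification, translation),
        pseudo,
    )


def acidification_fold_change(
    cond: pd.DataFrame,
    translation: str = "cycloheximide",
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene shock-with-acidification vs shock-without, one translation state.

    Both numerator and denominator are heat-shock conditions; translation
    state must match between them, since translation inhibition is what
    unmasks the acidification dependence of Hsf1 targets.
    """
    return _ratio(
        cond,
        _condition_key("shock", "allowed", translation),
        _condition_key("shock", "prevented", translation),
        pseudo,
    )


# ---------------------------------------------------------------------------
# Regulon scoring

def exclude_core_regulon_genes(
    regulons: list[RegulonSet],
    core_names: tuple[str, ...] = CORE_REGULONS,
) -> list[RegulonSet]:
    """Remove Hsf1/Msn2-4 member genes from every non-core regulon."""
    core = set()
    for r in regulons:
        if r.tf in core_names:
            core.update(r.genes)
    out = []
    for r in regulons:
        if r.tf in core_names:
            out.append(r)
        else:
            out.append(RegulonSet(r.tf, tuple(g for g in r.genes if g not in core),
                                  r.annotation))
    return out


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(values)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def score_regulons(
    induction: pd.Series,
    acid_fold: pd.Series,
    regulons: list[RegulonSet],
    min_size: int = MIN_REGULON_SIZE,
    core_names: tuple[str, ...] = CORE_REGULONS,
) -> pd.DataFrame:
    """Per-regulon induction and pH-sensitivity summary.

    For each regulon (after core-gene exclusion and the min-size rule):
    mean log2 induction fold change, median acidification fold change, an
    ECDF of acidification ratios, and a two-sided rank-sum p against the
    background of genes outside the Hsf1 and Msn2/4 regulons and outside the
    regulon itself.  Regulons falling below ``min_size`` after exclusion are
    dropped (reported via the ``dropped`` attribute on the result).
    """
    if not regulons:
        raise ValueError("empty regulon list")
    regulons = exclude_core_regulon_genes(regulons, core_names)
    universe = induction.index
    core_genes = set().union(*(r.genes for r in regulons if r.tf in core_names)) \
        if any(r.tf in core_names for r in regulons) else set()
    rows, dropped = [], []
    log_acid = np.log2(acid_fold)
    for r in regulons:
        members = [g for g in r.genes if g in universe]
        if len(members) < min_size:
            dropped.append({"tf": r.tf, "n_genes": len(members), "reason": "below min size"})
            continue
        ratios = acid_fold.loc[members].to_numpy(float)
        ratios = ratios[np.isfinite(ratios)]
        background = universe.difference(members).difference(core_genes)
        _, p = compare_class_ph(
            log_acid.loc[members].to_numpy(float),
            log_acid.loc[background].to_numpy(float),
        )
        xs, ys = _ecdf(ratios)
        rows.append(RegulonScore(
            tf=r.tf,
            n_genes=len(members),
            mean_log2_induction=float(np.nanmean(np.log2(induction.loc[members]))),
            median_acid_fold=float(np.median(ratios)),
            p_vs_background=float(p),
            ecdf_x=xs, ecdf_y=ys,
        ))
    table = pd.DataFrame([{
        "tf": s.tf, "n_genes": s.n_genes,
        "mean_log2_induction": s.mean_log2_induction,
        "median_acid_fold": s.median_acid_fold,
        "p_vs_background": s.p_vs_background,
    } for s in rows])
    table.attrs["dropped"] = dropped
    table.attrs["scores"] = rows
    return table


def test_regulon_vs_background(
    regulon_ratios,
    background_ratios,
    min_size: int = MIN_REGULON_SIZE,
) -> tuple[float, float]:
    """Two-sided rank-sum test of a regulon's log ratios against background.

    The groups must be disjoint samples (a gene cannot sit on both sides).
    Returns (U, p); shares the rank-sum implementation used for the
    single-cell class comparison.
    """
    if isinstance(regulon_ratios, pd.Series) and isinstance(background_ratios, pd.Series):
        overlap = regulon_ratios.index.intersection(background_ratios.index)
        if len(overlap):
            raise ValueError(
                f"regulon and background overlap on {len(overlap)} genes, e.g. {list(overlap[:3])}"
            )
    a = np.asarray(regulon_ratios, dtype=float)
    b = np.asarray(background_ratios, dtype=float)
    if len(a) < min_size or len(b) < min_size:
        raise ValueError(
            f"regulon and background need >= {min_size} genes, got {len(a)} and {len(b)}"
        )
    return compare_class_ph(np.log2(a), np.log2(b))
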