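"""Spectral counting with shared-peptide apportionment and % total peptides.

Quantification is label-free spectral counting: every retained PSM contributes
one count. Counts from peptides unique to a protein group accrue directly;
counts from shared peptides are apportioned among the groups that contain the
peptide in proportion to each group's unique evidence *in the same sample*
(an equal split when no involved group has unique evidence there). Apportioned
counts are normalised to % of the sample total and replicate-averaged into
per-fraction profiles (mean ± sample s.d.).

Conservation is exact by construction: within each shared peptide the last
involved group receives the spectra not yet allocated, so column sums equal
retained PSM totals bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .inference import ProteinGroup

__all__ = [
    "CountedSpectra",
    "QuantMatrix",
    "count_spectra",
    "apportion_shared",
    "percent_total",
    "average_replicates",
    "quantify_pipeline",
]


def _sample_key(sample: str, replicate: int) -> str:
    return f"{sample}:{replicate}"


@dataclass
class CountedSpectra:
    """Raw spectral counts split by peptide class.

    ``raw_unique``/``raw_shared`` are group x sample count matrices (a shared
    peptide's spectra are tallied against every involved group pending
    apportionment). ``shared_detail`` keeps per-(peptide, sample) counts so
    apportionment can be recomputed peptide by peptide; ``distinct_unique``
    counts distinct unique peptides observed per group and sample (the
    alternative apportionment weight).
    """

    raw_unique: pd.DataFrame
    raw_shared: pd.DataFrame
    shared_detail: dict[tuple[str, str], int]
    shared_owners: dict[str, tuple[str, ...]]
    distinct_unique: pd.DataFrame


def _psm_frame(psms) -> pd.DataFrame:
    """Normalise PSM input (records or a DataFrame) to peptide/sample columns."""
    if isinstance(psms, pd.DataFrame):
        df = psms.loc[:, ["peptide", "sample", "replicate"]].copy()
    else:
        df = pd.DataFrame(
            {
                "peptide": [r.peptide for r in psms],
                "sample": [r.sample for r in psms],
                "replicate": [r.replicate for r in psms],
            }
        )
    df["col"] = df["sample"].astype(str) + ":" + df["replicate"].astype(str)
    return df


def count_spectra(
    psms,  # sequence of PSMRecord-like, or a DataFrame with the same columns
    groups: Sequence[ProteinGroup],
    classification: Mapping[str, tuple],
    sample_order: Optional[Sequence[str]] = None,
) -> CountedSpectra:
    """Tally one count per PSM into unique or shared evidence.

    Every PSM peptide must be classified (orphans are filtered upstream);
    an unclassified peptide raises a consistency error naming it. The result
    is invariant to PSM order.
    """
    reps = [g.representative for g in groups]
    df = _psm_frame(psms)
    cols = list(sample_order) if sample_order is not None else list(
        dict.fromkeys(df["col"])
    )
    unknown_cols = set(df["col"]) - set(cols)
    if unknown_cols:
        raise ParameterError(f"sample {sorted(unknown_cols)[0]} not in sample_order")
    unclassified = set(df["peptide"]) - set(classification)
    if unclassified:
        raise ConsistencyError(f"unclassified peptide {sorted(unclassified)[0]!r}")

    kind = df["peptide"].map(lambda p: classification[p][0])
    raw_unique = pd.DataFrame(0.0, index=reps, columns=cols)
    raw_shared = pd.DataFrame(0.0, index=reps, columns=cols)
    distinct_unique = pd.DataFrame(0.0, index=reps, columns=cols)

    uni = df[kind == "unique"]
    if len(uni):
        owner = uni["peptide"].map(lambda p: classification[p][1])
        tallies = uni.groupby([owner.rename("owner"), uni["col"]]).agg(
            count=("peptide", "size"), distinct=("peptide", "nunique")
        )
        for (rep, col), row in tallies.iterrows():
            raw_unique.loc[rep, col] = float(row["count"])
            distinct_unique.loc[rep, col] = float(row["distinct"])

    shared_detail: dict[tuple[str, str], int] = {}
    shared_owners: dict[str, tuple[str, ...]] = {}
    sh = df[kind == "shared"]
    if len(sh):
        for (pep, col), n in sh.groupby(["peptide", "col"]).size().items():
            shared_detail[(pep, col)] = int(n)
            owners = tuple(sorted(classification[pep][1]))
            shared_owners[pep] = owners
            for rep in owners:
                raw_shared.loc[rep, col] += int(n)

    return CountedSpectra(raw_unique, raw_shared, shared_detail, shared_owners, distinct_unique)


def apportion_shared(counts: CountedSpectra, mode: str = "spectra") -> pd.DataFrame:
    """Distribute shared-peptide spectra by the proportion of unique evidence.

    For a shared peptide with ``s`` spectra in a sample, group ``g`` among the
    involved groups receives ``s * u_g / sum(u)`` where ``u_g`` is ``g``'s
    unique spectral count in that sample (``mode="spectra"``, the default) or
    its distinct unique-peptide count (``mode="peptides"``). When no involved
    group has unique evidence in the sample the spectra are split equally.

    Conservation is exact: the integer spectrum total per sample is known, and
    the sub-ulp floating-point residual of each column is folded into its
    largest entry, so column sums equal the retained PSM totals bit-for-bit.
    """
    if mode not in ("spectra", "peptides"):
        raise ParameterError(f"unknown apportionment mode {mode!r}")
    weights = counts.raw_unique if mode == "spectra" else counts.distinct_unique
    apportioned = counts.raw_unique.copy()
    shared_total = dict.fromkeys(apportioned.columns, 0)
    for (pep, col), s in sorted(counts.shared_detail.items()):
        owners = counts.shared_owners[pep]
        u = np.array([weights.loc[rep, col] for rep in owners], dtype=float)
        if u.sum() == 0:
            alloc = np.full(len(owners), s / len(owners))
        else:
            alloc = s * u / u.sum()
        alloc[-1] = s - alloc[:-1].sum()
        shared_total[col] += s
        for rep, a in zip(owners, alloc):
            apportioned.loc[rep, col] += a
    targets = {
        col: counts.raw_unique[col].sum() + shared_total[col]
        for col in apportioned.columns
    }
    _fold_residual(apportioned, targets)
    return apportioned


def _fold_residual(apportioned: pd.DataFrame, targets: Mapping[str, float]) -> None:
    """Fold each column's sub-ulp rounding residual into its smallest positive
    entry (where the ulp is fine enough to absorb it) so that
    ``apportioned[col].sum()`` equals the integer spectrum total exactly."""
    for col in apportioned.columns:
        for _ in range(25):
            resid = targets[col] - apportioned[col].sum()
            if resid == 0:
                break
            positive = apportioned[col][apportioned[col] > 0]
            receiver = positive.idxmin() if len(positive) else apportioned[col].idxmax()
            apportioned.loc[receiver, col] += resid


def percent_total(apportioned: pd.DataFrame) -> pd.DataFrame:
    """Per-sample % of total apportioned counts (columns sum to 100)."""
    totals = apportioned.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ParameterError(f"sample {empty.index[0]!r} has no retained spectra")
    return 100.0 * apportioned / totals


def average_replicates(
    percent: pd.DataFrame,
    fraction_order: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate mean and sample s.d. of % total peptides per fraction.

    Sample columns are ``fraction:replicate``; a group absent from a
    replicate contributes 0 for it. Sample s.d. uses the n-1 denominator and
    is 0 for single-replicate fractions.
    """
    frac_of = {c: c.rsplit(":", 1)[0] for c in percent.columns}
    if fraction_order is None:
        fraction_order = list(dict.fromkeys(frac_of.values()))
    mean = pd.DataFrame(index=percent.index, columns=list(fraction_order), dtype=float)
    sd = pd.DataFrame(index=percent.index, columns=list(fraction_order), dtype=float)
    for frac in fraction_order:
        cols = [c for c in percent.columns if frac_of[c] == frac]
        if not cols:
            raise ParameterError(f"fraction {frac!r} has no replicates")
        block = percent[cols]
        mean[frac] = block.mean(axis=1)
        sd[frac] = block.std(axis=1, ddof=1).fillna(0.0) if len(cols) > 1 else 0.0
    return mean, sd


@dataclass
class QuantMatrix:
    """Full quantification result for one run."""

    groups: list[ProteinGroup]
    samples: list[str]
    raw_unique: pd.DataFrame
    raw_shared: pd.DataFrame
    apportioned: pd.DataFrame
    percent: pd.DataFrame
    profile_mean: pd.DataFrame
    profile_sd: pd.DataFrame
    dropped_groups: list[str]


def quantify_pipeline(
    psms,
    groups: Sequence[ProteinGroup],
    classification: Mapping[str, tuple],
    sample_order: Optional[Sequence[str]] = None,
    fraction_order: Optional[Sequence[str]] = None,
    mode: str = "spectra",
) -> QuantMatrix:
    """Counting, apportionment, normalisation and replicate averaging.

    Groups with zero evidence across every sample after filtering are dropped
    from the matrices and listed in ``dropped_groups``.
    """
    counts = count_spectra(psms, groups, classification, sample_order)
    apportioned = apportion_shared(counts, mode=mode)
    totals = {col: apportioned[col].sum() for col in apportioned.columns}
    evidence = apportioned.sum(axis=1)
    dropped = [rep for rep in apportioned.index if evidence[rep] == 0]
    keep = [rep for rep in apportioned.index if evidence[rep] > 0]
    apportioned = apportioned.loc[keep].copy()
    # dropped rows are exactly zero; re-fold the residual the changed
    # summation order introduces so sample totals stay exact
    _fold_residual(apportioned, totals)
    percent = percent_total(apportioned)
    mean, sd = average_replicates(percent, fraction_order)
    kept_groups = [g for g in groups if g.representative in keep]
    return QuantMatrix(
        groups=kept_groups,
        samples=list(apportioned.columns),
        raw_unique=counts.raw_unique.loc[keep],
        raw_shared=counts.raw_shared.loc[keep],
        apportioned=apportioned,
        percent=percent,
        profile_mean=mean,
        profile_sd=sd,
        dropped_groups=dropped,
    )
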