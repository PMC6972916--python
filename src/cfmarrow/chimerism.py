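"""Allograft chimerism monitoring from expressed SNP allele frequencies.

After an allogeneic stem-cell transplant, transcripts made by engrafting
donor cells carry the donor's genotype.  At SNPs where host and donor
genotypes differ, the reference-allele frequency observed in cf-mRNA moves
from the host's value (1.0 hom-ref, 0.5 het, 0.0 hom-alt) toward the
donor's as donor marrow output takes over.  This module classifies per-day
genotypes from allele counts, detects host-to-donor genotype transitions
(e.g. hom-ref -> het), and averages frequency trajectories over SNPs
sharing a transition label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "allele_frequency",
    "classify_genotype",
    "classify_table",
    "detect_transitions",
    "average_trajectory",
]

GENOTYPES = ("hom-ref", "het", "hom-alt")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"snp", "day", "ref_count", "alt_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"allele-count table lacks columns: {sorted(missing)}")
    if (table[["ref_count", "alt_count"]].to_numpy() < 0).any():
        raise ValueError("allele counts must be non-negative")
    return table


def allele_frequency(table: pd.DataFrame) -> pd.DataFrame:
    """Reference-allele frequency ref/(ref+alt) per SNP per day.

    Entries with zero depth get NaN frequency — flagged as undefined, never
    imputed.  Returns the input with ``depth`` and ``frequency`` columns
    appended.
    """
    table = _validate(table).copy()
    depth = table["ref_count"] + table["alt_count"]
    table["depth"] = depth
    table["frequency"] = np.where(depth > 0, table["ref_count"] / depth.where(depth > 0), np.nan)
    return table


def classify_genotype(
    frequency: float,
    depth: int,
    hom_threshold: float = 0.9,
    min_depth: int = 10,
) -> str:
    """Call a genotype from one reference-allele frequency observation.

    ``>= hom_threshold`` -> hom-ref; ``<= 1 - hom_threshold`` -> hom-alt;
    otherwise het.  Depth below ``min_depth`` (or undefined frequency)
    yields ``"ambiguous"`` regardless of the frequency.
    """
    if depth < min_depth or not np.isfinite(frequency):
        return "ambiguous"
    if not 0.0 <= frequency <= 1.0:
        raise ValueError("frequency must lie in [0, 1]")
    if frequency >= hom_threshold:
        return "hom-ref"
    # compare the alt-allele frequency against the same threshold, keeping the
    # two homozygous boundaries exactly symmetric in floating point
    if 1.0 - frequency >= hom_threshold:
        return "hom-alt"
    return "het"


def classify_table(
    table: pd.DataFrame, hom_threshold: float = 0.9, min_depth: int = 10
) -> pd.DataFrame:
    """Vectorized :func:`classify_genotype` over a frequency table."""
    if "frequency" not in table.columns:
        table = allele_frequency(table)
    out = table.copy()
    out["call"] = [
        classify_genotype(f, d, hom_threshold, min_depth)
        for f, d in zip(out["frequency"], out["depth"])
    ]
    return out


def _consensus(calls: pd.Series) -> str:
    """Majority non-ambiguous call; ties or no information -> ambiguous."""
    informative = calls[calls != "ambiguous"]
    if informative.empty:
        return "ambiguous"
    counts = informative.value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        return "ambiguous"
    return str(counts.index[0])


def detect_transitions(
    calls: pd.DataFrame,
    transplant_day: int = 0,
    persistence: int = 2,
) -> pd.DataFrame:
    """Per-SNP genotype transition labels and transition days.

    The pre-transplant consensus is the majority non-ambiguous call over
    days before ``transplant_day`` (ties -> indeterminate).  The
    post-transplant consensus is the call held over the final run of at
    least ``persistence`` consecutive informative post-transplant days;
    the transition day is the first post-transplant day starting a run of
    ``persistence`` informative days agreeing with that consensus, which
    suppresses single-day noise flips.  SNPs whose pre and post consensus
    agree get label ``"none"``; SNPs lacking an informative consensus on
    either side get ``"indeterminate"``.

    Parameters
    ----------
    calls
        Output of :func:`classify_table` (columns snp, day, call, ...).

    Returns
    -------
    DataFrame indexed by SNP with columns ``pre``, ``post``, ``label``,
    ``transition_day`` (NaN when no transition).
    """
    if "call" not in calls.columns:
        raise ValueError("expected a classified table with a 'call' column")
    rows = []
    for snp, sub in calls.sort_values("day").groupby("snp", sort=True):
        pre = _consensus(sub.loc[sub["day"] < transplant_day, "call"])
        post_sub = sub[sub["day"] >= transplant_day]
        informative = post_sub[post_sub["call"] != "ambiguous"]

        post = "ambiguous"
        transition_day: float | int = np.nan
        if len(informative) >= persistence:
            seq = informative["call"].to_list()
            days = informative["day"].to_list()
            # final run of agreeing informative days defines the post consensus
            run_len = 1
            while run_len < len(seq) and seq[-run_len - 1] == seq[-1]:
                run_len += 1
            if run_len >= persistence:
                post = seq[-1]
                for i in range(len(seq) - persistence + 1):
                    if all(c == post for c in seq[i : i + persistence]):
                        transition_day = days[i]
                        break

        if pre == "ambiguous" or post == "ambiguous":
            label = "indeterminate"
            transition_day = np.nan
        elif pre == post:
            label = "none"
            transition_day = np.nan
        else:
            label = f"{pre}->{post}"
        rows.append((snp, pre, post, label, transition_day))
    out = pd.DataFrame(
        rows, columns=["snp", "pre", "post", "label", "transition_day"]
    ).set_index("snp")
    return out


def average_trajectory(
    frequencies: pd.DataFrame, snp_set: list[str]
) -> pd.DataFrame:
    """Mean reference-allele frequency over a SNP set, per day.

    Arithmetic mean over SNPs with a defined frequency at each day, with
    the standard error across SNPs and the number of informative SNPs;
    days where no SNP is informative keep NaN mean (flagged via
    ``n_snps == 0``).
    """
    if not snp_set:
        raise ValueError("snp_set is empty")
    if "frequency" not in frequencies.columns:
        frequencies = allele_frequency(frequencies)
    sub = frequencies[frequencies["snp"].isin(set(snp_set))]
    missing = set(snp_set) - set(sub["snp"])
    if missing:
        raise ValueError(f"SNPs absent from table: {sorted(missing)[:5]}")

    wide = sub.pivot(index="snp", columns="day", values="frequency")
    n = wide.notna().sum(axis=0)
    out = pd.DataFrame(
        {
            "mean": wide.mean(axis=0),
            "sem": wide.std(axis=0, ddof=1) / np.sqrt(n.clip(lower=1)),
            "n_snps": n,
        }
    )
    out.index.name = "day"
    return out
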