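"""Binary gene x patient alteration matrices, built per target signature.

A gene is altered in a patient if it carries at least one non-silent
mutation there — excluding mutations attributed to the target signature
(both its cloud and dispersed contexts), and excluding indels when the
target's underlying signature is one of the indel-heavy ones (3 and 8 by
default) — or if the (patient, gene) pair is annotated as biallelically
inactivated.  Biallelic annotations bypass both exclusions.  Genes altered
in fewer than ``frequency_min`` of patients are dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: signatures whose associations are tested without indels
INDEL_HEAVY_SIGNATURES = ("3", "8")


def underlying_signature(target: str) -> str:
    """Strip the C/D context suffix from a signature-context label."""
    if target and target[-1] in ("C", "D"):
        return target[:-1]
    return target


def build_matrix(mutations: pd.DataFrame,
                 biallelic: pd.DataFrame | None,
                 target: str,
                 drop_indels: bool | None = None,
                 frequency_min: float = 0.01,
                 patients: list[str] | None = None) -> pd.DataFrame:
    """Build the alteration matrix for one target signature-context.

    ``mutations`` must carry sample, gene, consequence, variant_type and
    ``assigned_signature`` columns.  ``biallelic`` is a (sample, gene)
    pair table or None.  ``drop_indels`` defaults to True exactly when the
    target's underlying signature is indel-heavy (3 or 8).  ``patients``
    fixes the column universe (default: samples seen in the mutation
    table), so the frequency filter has a well-defined denominator.
    """
    sig = underlying_signature(target)
    if not sig:
        raise ValueError("unknown target signature")
    if drop_indels is None:
        drop_indels = sig in INDEL_HEAVY_SIGNATURES

    df = mutations
    if patients is None:
        patients = sorted(df["sample"].unique())
    if not patients:
        raise ValueError("empty patient set")

    keep = df["gene"].astype(str).ne("") & df["consequence"].eq("non-silent")
    keep &= df["assigned_signature"].astype(str).ne(sig)
    if drop_indels:
        keep &= df["variant_type"].ne("indel")
    kept = df[keep]

    genes = sorted(set(kept["gene"].astype(str)))
    if biallelic is not None and len(biallelic):
        genes = sorted(set(genes) | set(biallelic["gene"].astype(str)))
    M = pd.DataFrame(0, index=genes, columns=patients, dtype=np.int8)
    if len(kept):
        hits = kept[kept["sample"].isin(patients)]
        for g, s in zip(hits["gene"].astype(str), hits["sample"]):
            M.loc[g, s] = 1
    if biallelic is not None:
        for s, g in zip(biallelic["sample"], biallelic["gene"].astype(str)):
            if s in M.columns:
                M.loc[g, s] = 1
    return _frequency_filter(M, frequency_min)


def _frequency_filter(M: pd.DataFrame, frequency_min: float) -> pd.DataFrame:
    freq = M.mean(axis=1)
    dropped = int((freq < frequency_min).sum())
    if dropped:
        logger.info("frequency filter dropped %d genes below %.3f", dropped, frequency_min)
    out = M.loc[freq >= frequency_min]
    out.attrs["frequency_min"] = frequency_min
    return out


def subset_samples(matrix: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Column-subset an alteration matrix, re-applying the frequency filter."""
    missing = [s for s in sample_ids if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing[:5]}")
    sub = matrix[sample_ids]
    return _frequency_filter(sub, matrix.attrs.get("frequency_min", 0.01))
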