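"""Signature attribution and exposure phenotypes.

Turns a table of somatic mutations into per-patient signature "exposure"
phenotypes in four steps:

1. split mutations into clustered ("cloud", C) and isolated ("dispersed", D)
   groups by inter-mutation distance on the same chromosome of the same
   sample;
2. attribute each single-base substitution to one signature of a fixed
   catalog with a per-patient multinomial mixture model fit by EM, taking
   the majority assignment over repeated random initialisations (31 by
   default);
3. count mutations per patient and per signature-context label (``"2C"``,
   ``"13D"``, ...) into an exposure table;
4. keep only abundant signature-contexts (share of its group's mutations
   strictly above a threshold, 10% by default) and turn each retained
   label's counts into a z-scored log10 phenotype vector.

The mixture model treats each patient's dispersed and cloud mutations alike:
channel counts are modelled as draws from a convex combination of the
catalog's channel distributions.  Sequential dependency between nearby
mutations is deliberately not modelled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import N_CHANNELS, validate_catalog

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt",
    "variant_type", "consequence", "gene",
]

#: COSMIC v2 signatures reported active in breast cancer.
BRCA_SIGNATURES = ("1", "2", "3", "5", "6", "8", "13", "17", "18", "20", "26", "30")


@dataclass
class PhenotypeVector:
    """Per-patient standardized phenotype for one signature-context.

    ``values`` is indexed by patient id; construction guarantees mean 0 and
    unit sample (n-1) standard deviation.  ``log_base`` and ``pseudocount``
    record the transform provenance.
    """

    label: str
    values: pd.Series
    log_base: float = 10.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        if len(v) >= 2:
            assert abs(v.mean()) < 1e-8, "phenotype not centred"
            assert abs(v.std(ddof=1) - 1.0) < 1e-8, "phenotype not unit-sd"
        self.values = v


def split_cloud_dispersed(mutations: pd.DataFrame, distance_bp: int = 1000) -> pd.Series:
    """Label each mutation C (cloud) or D (dispersed).

    A mutation is a cloud mutation iff another mutation of the same sample
    lies on the same chromosome within ``distance_bp`` bases.  Input must be
    sorted by (sample, chrom, pos); the labelling is symmetric, so reversing
    the input order yields identical labels per mutation.
    """
    if distance_bp <= 0:
        raise ValueError("distance_bp must be positive")
    key = mutations[["sample", "chrom", "pos"]]
    if not key.reset_index(drop=True).equals(
        key.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)
    ):
        raise ValueError("mutations must be sorted by (sample, chrom, pos)")

    pos = mutations["pos"].to_numpy(dtype=np.int64)
    same_block = (
        (mutations["sample"].to_numpy()[1:] == mutations["sample"].to_numpy()[:-1])
        & (mutations["chrom"].to_numpy()[1:] == mutations["chrom"].to_numpy()[:-1])
    )
    close = same_block & (np.abs(pos[1:] - pos[:-1]) <= distance_bp)
    is_cloud = np.zeros(len(mutations), dtype=bool)
    is_cloud[1:] |= close
    is_cloud[:-1] |= close
    return pd.Series(np.where(is_cloud, "C", "D"), index=mutations.index, name="context_group")


def _em_fit(counts: np.ndarray, P: np.ndarray, rng: np.random.Generator,
            max_iter: int = 500, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM for multinomial mixture weights given channel counts.

    counts: (96,) channel counts for one patient; P: (n_sig, 96) catalog.
    Returns (weights, posterior per channel (n_sig, 96), converged flag).
    """
    n_sig = P.shape[0]
    pi = rng.dirichlet(np.ones(n_sig))
    logP = np.log(np.maximum(P, 1e-300))
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step: posterior over signatures for each channel
        logw = np.log(np.maximum(pi, 1e-300))[:, None] + logP  # (n_sig, 96)
        m = logw.max(axis=0)
        post = np.exp(logw - m)
        norm = post.sum(axis=0)
        post /= norm
        ll = float(np.sum(counts * (m + np.log(norm))))
        # M-step
        resp = post @ counts  # expected mutations per signature
        pi = resp / resp.sum()
        if ll - prev < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev = ll
    return pi, post, converged


def attribute_mutations(
    mutations: pd.DataFrame,
    catalog: pd.DataFrame,
    n_restarts: int = 31,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each SNV to a catalog signature by per-patient mixture EM.

    Each patient's SNV channel counts are fit with a multinomial mixture
    over the catalog signatures; each mutation is assigned its
    maximum-posterior signature.  The final assignment is the majority vote
    over ``n_restarts`` random initialisations (ties broken toward the
    lower catalog index for determinism).

    Requires a ``channel`` column (0-based SBS channel index) on SNV rows.
    Indels receive no signature assignment (empty string).

    Returns ``(attributed, exposures)`` where ``attributed`` is the input
    with an ``assigned_signature`` column added and ``exposures`` holds the
    mean fitted mixture weights per patient (patients x signatures).
    """
    cat = validate_catalog(catalog)
    sig_ids = [str(c) for c in cat.columns]
    P = cat.values.T  # (n_sig, 96)
    n_sig = len(sig_ids)

    out = mutations.copy()
    is_snv = out["variant_type"].eq("SNV") if "variant_type" in out else pd.Series(True, index=out.index)
    if is_snv.any() and "channel" not in out.columns:
        raise ValueError("SNV records need a 'channel' column (0-based SBS channel index)")
    assigned = np.full(len(out), "", dtype=object)

    rng = np.random.default_rng(seed)
    weights_rows: dict[str, np.ndarray] = {}
    patients = out["sample"].unique()
    for patient in patients:
        mask = (out["sample"].to_numpy() == patient) & is_snv.to_numpy()
        if not mask.any():
            weights_rows[patient] = np.full(n_sig, np.nan)
            continue
        channels = out.loc[mask, "channel"].to_numpy(dtype=np.int64)
        if (channels < 0).any() or (channels >= N_CHANNELS).any():
            raise ValueError(f"channel index out of range for patient {patient}")
        counts = np.bincount(channels, minlength=N_CHANNELS).astype(float)
        votes = np.zeros((len(channels), n_sig), dtype=np.int32)
        weight_sum = np.zeros(n_sig)
        for _ in range(n_restarts):
            pi, post, converged = _em_fit(counts, P, rng)
            if not converged:
                warnings.warn(f"EM did not converge for patient {patient}; using best attained",
                              RuntimeWarning, stacklevel=2)
            weight_sum += pi
            map_sig = post.argmax(axis=0)  # per channel
            votes[np.arange(len(channels)), map_sig[channels]] += 1
        weights_rows[patient] = weight_sum / n_restarts
        assigned[np.flatnonzero(mask)] = [sig_ids[i] for i in votes.argmax(axis=1)]

    out["assigned_signature"] = assigned
    exposures = pd.DataFrame.from_dict(weights_rows, orient="index", columns=sig_ids)
    exposures.index.name = "sample"
    return out, exposures


def build_exposure_table(attributed: pd.DataFrame,
                         patients: list[str] | None = None) -> pd.DataFrame:
    """Count mutations per (patient, signature-context label).

    Labels combine the assigned signature and the cloud/dispersed group,
    e.g. ``"2C"``.  Rows cover ``patients`` if given (missing ones all
    zero), else the patients present in the input.
    """
    df = attributed
    has = df[(df.get("assigned_signature", "") != "") & df["context_group"].isin(["C", "D"])]
    if len(has):
        labels = has["assigned_signature"].astype(str) + has["context_group"].astype(str)
        table = pd.crosstab(has["sample"], labels)
    else:
        table = pd.DataFrame()
    if patients is not None:
        table = table.reindex(patients, fill_value=0)
    table = table.fillna(0).astype(int)
    table.index.name = "sample"
    return table


def filter_abundant(exposures: pd.DataFrame, threshold: float = 0.10) -> list[str]:
    """Retain signature-context labels whose within-group share exceeds ``threshold``.

    For each group (C and D separately) the share of the group's total
    mutations attributed to each signature is computed; a label like
    ``"5D"`` is retained iff that share is strictly greater than the
    threshold.  A group with zero mutations retains nothing (warned).
    """
    retained: list[str] = []
    cols = list(exposures.columns)
    for group in ("C", "D"):
        gcols = [c for c in cols if c.endswith(group)]
        total = int(exposures[gcols].to_numpy().sum()) if gcols else 0
        if total == 0:
            warnings.warn(f"no mutations in group {group}; no labels retained",
                          RuntimeWarning, stacklevel=2)
            continue
        for c in gcols:
            if exposures[c].sum() / total > threshold:
                retained.append(c)
    return sorted(retained, key=lambda s: (s[-1], s[:-1]))


def make_phenotype(exposures: pd.DataFrame, label: str,
                   pseudocount: float = 1.0) -> PhenotypeVector:
    """z-score of log10(count + pseudocount) for one signature-context.

    Uses the sample (n-1) standard deviation.  Raises if the counts are
    constant (the phenotype would be undefined).
    """
    if label not in exposures.columns:
        raise KeyError(f"label {label!r} not in exposure table")
    counts = exposures[label].astype(float)
    v = np.log10(counts + pseudocount)
    sd = v.std(ddof=1)
    if counts.nunique() <= 1 or not np.isfinite(sd) or sd < 1e-12:
        raise ValueError(f"constant counts for {label!r}: phenotype undefined")
    z = (v - v.mean()) / sd
    return PhenotypeVector(label=label, values=z, log_base=10.0, pseudocount=pseudocount)
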