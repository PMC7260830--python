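"""Single-base-substitution channel definitions and signature catalogs.

Mutational signatures are probability distributions over the 96 standard
single-base-substitution channels: six pyrimidine-centred substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 possible 5'/3' flanking
base combinations.  The canonical channel ordering used throughout this
package groups channels by substitution type and, within a type, sorts the
trinucleotide contexts alphabetically — the ordering used by the COSMIC v2
signature tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel labels like ``"A[C>A]A"`` in COSMIC v2 order (96 entries).
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}

N_CHANNELS = 96


def channel_of(context5: str, ref: str, alt: str, context3: str) -> int:
    """Return the 0-based channel index for a single-base substitution.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand, as is standard for SBS channel assignment.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ref, alt = ref.upper(), alt.upper()
    context5, context3 = context5.upper(), context3.upper()
    if ref in ("G", "A"):
        ref, alt = comp[ref], comp[alt]
        context5, context3 = comp[context3], comp[context5]
    label = f"{context5}[{ref}>{alt}]{context3}"
    try:
        return CHANNEL_INDEX[label]
    except KeyError:
        raise ValueError(f"not a valid SBS channel: {label!r}") from None


def validate_catalog(catalog: pd.DataFrame, *, atol: float = 1e-9) -> pd.DataFrame:
    """Validate a signature catalog (channels x signatures).

    Accepts either orientation and returns the catalog as a 96-row frame
    indexed by channel label, one column per signature.  Each signature
    column must be a probability distribution over the 96 channels.
    """
    if catalog.shape[0] != N_CHANNELS and catalog.shape[1] == N_CHANNELS:
        catalog = catalog.T
    if catalog.shape[0] != N_CHANNELS:
        raise ValueError(
            f"signature catalog must have {N_CHANNELS} channels, got shape {catalog.shape}"
        )
    cat = catalog.astype(float).copy()
    if list(cat.index) != list(CHANNELS):
        if set(cat.index) == set(CHANNELS):
            cat = cat.loc[list(CHANNELS)]
        else:
            # positional input: trust the ordering, attach canonical labels
            cat.index = list(CHANNELS)
    if (cat.values < 0).any():
        raise ValueError("signature catalog contains negative probabilities")
    sums = cat.sum(axis=0).values
    if not np.allclose(sums, 1.0, atol=max(atol, 1e-6)):
        bad = cat.columns[~np.isclose(sums, 1.0, atol=max(atol, 1e-6))].tolist()
        raise ValueError(f"signature columns do not sum to 1: {bad}")
    return cat
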