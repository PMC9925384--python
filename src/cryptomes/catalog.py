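"""Reference SBS signature catalog.

The catalog is a 96-row table of per-channel probabilities, one column per
named signature.  For real analyses users supply COSMIC vectors as a TSV;
the built-in catalog contains synthetic approximations of the signatures
active in normal intestinal epithelium (clock-like SBS1/SBS5, oxidative
SBS18, APOBEC SBS2/SBS13, chemotherapy SBS17b/SBS35, flat SBS40, SBS41 and
colibactin SBS88) with the characteristic peaks of each process, adequate
for simulation and attribution at desk scale but not identical to COSMIC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trinuc import BASES, CHANNELS, CHANNEL_INDEX


def _vector(peaks: dict[str, float], background: float = 0.0) -> np.ndarray:
    v = np.full(len(CHANNELS), background / len(CHANNELS))
    for channel, weight in peaks.items():
        v[CHANNEL_INDEX[channel]] += weight
    return v / v.sum()


def _sub_channels(sub: str, five: str = BASES, three: str = BASES) -> list[str]:
    return [f"{f}[{sub}]{t}" for f in five for t in three]


def default_catalog() -> pd.DataFrame:
    """Synthetic reference catalog (96 channels x 10 signatures)."""
    sig = {}

    # 5-methylcytosine deamination clock: C>T at NpCpG
    sig["SBS1"] = _vector(
        {f"{f}[C>T]G": w for f, w in zip(BASES, (0.20, 0.26, 0.18, 0.26))},
        background=0.10,
    )
    # APOBEC C>T at TpCpN
    sig["SBS2"] = _vector(
        {"T[C>T]A": 0.26, "T[C>T]C": 0.22, "T[C>T]G": 0.07, "T[C>T]T": 0.40},
        background=0.05,
    )
    # flat, mild T>C tilt
    flat = np.ones(len(CHANNELS))
    tilt = np.array([1.8 if c[2:5] == "T>C" else 1.0 for c in CHANNELS])
    sig["SBS5"] = flat * tilt / (flat * tilt).sum()
    # APOBEC C>G (and some C>A) at TpCpN
    v13 = {f"T[C>G]{t}": w for t, w in zip(BASES, (0.22, 0.16, 0.05, 0.40))}
    v13.update({f"T[C>A]{t}": 0.025 for t in BASES})
    sig["SBS13"] = _vector(v13, background=0.07)
    # 5-FU: T>G at NpTpT
    sig["SBS17b"] = _vector(
        {f"{f}[T>G]T": w for f, w in zip(BASES, (0.18, 0.34, 0.14, 0.24))},
        background=0.10,
    )
    # oxidative damage: broad C>A with 5' purine preference
    v18 = {c: (1.6 if c[0] in "AG" else 0.8) for c in _sub_channels("C>A")}
    sig["SBS18"] = _vector(v18, background=0.12)
    # platinum: mixed C>A / C>T, broad
    v35 = {c: 0.5 for c in _sub_channels("C>A")}
    v35.update({c: 0.3 for c in _sub_channels("C>T")})
    sig["SBS35"] = _vector(v35, background=0.25)
    # featureless flat signature
    sig["SBS40"] = np.full(len(CHANNELS), 1.0 / len(CHANNELS))
    # T>A dominated
    sig["SBS41"] = _vector({c: 1.0 for c in _sub_channels("T>A")}, background=0.20)
    # colibactin: T>C and T>A at ApTpN
    v88 = {f"A[T>C]{t}": 0.14 for t in BASES}
    v88.update({f"A[T>A]{t}": 0.09 for t in BASES})
    sig["SBS88"] = _vector(v88, background=0.08)

    cat = pd.DataFrame(sig, index=pd.Index(CHANNELS, name="channel"))
    validate_catalog(cat)
    return cat


def validate_catalog(catalog: pd.DataFrame) -> None:
    """Check shape, non-negativity and per-signature normalization."""
    if list(catalog.index) != list(CHANNELS):
        raise ValueError("catalog must be indexed by the 96 channels in catalog order")
    if (catalog.values < 0).any():
        raise ValueError("catalog contains negative probabilities")
    sums = catalog.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"signatures not normalized: {dict(bad)}")


def load_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", index_col=0)
    cat.index.name = "channel"
    validate_catalog(cat)
    return cat


def save_catalog(catalog: pd.DataFrame, path) -> None:
    validate_catalog(catalog)
    catalog.to_csv(path, sep="\t")
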