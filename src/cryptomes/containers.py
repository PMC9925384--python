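"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns required in the per-variant info table
VARIANT_INFO_COLS = ["variant_id", "chrom", "pos", "ref", "alt", "variant_class"]

#: columns required in the sample metadata table
METADATA_COLS = ["sample_id", "patient", "age_years", "region", "celiac", "mean_coverage"]

REGIONS = ("duodenum", "jejunum", "ileum")


@dataclass
class VariantCounts:
    """Per-variant read counts across crypt samples.

    ``info`` holds one row per variant (chrom, 1-based pos, ref, alt,
    variant_class in {SBS, ID}); ``alt`` and ``depth`` are variant x sample
    integer matrices indexed by ``variant_id`` with identical shape.
    """

    info: pd.DataFrame
    alt: pd.DataFrame
    depth: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_INFO_COLS if c not in self.info.columns]
        if missing:
            raise ValueError(f"variant info missing columns {missing}")
        if not self.info["variant_id"].is_unique:
            raise ValueError("variant_id must be unique")
        if (self.info["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos >= 1 required")
        if list(self.alt.index) != list(self.info["variant_id"]):
            self.alt = self.alt.loc[self.info["variant_id"]]
        if list(self.depth.index) != list(self.info["variant_id"]) or list(
            self.depth.columns
        ) != list(self.alt.columns):
            self.depth = self.depth.loc[self.info["variant_id"], self.alt.columns]
        if (self.alt.values < 0).any() or (self.alt.values > self.depth.values).any():
            raise ValueError("require 0 <= alt <= depth for every cell")

    @property
    def samples(self) -> list[str]:
        return list(self.alt.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.info["variant_id"])

    def __len__(self) -> int:
        return len(self.info)

    def vaf(self) -> pd.DataFrame:
        """Per-cell VAF; NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.alt.values / self.depth.values
        return pd.DataFrame(v, index=self.alt.index, columns=self.alt.columns)

    def subset(self, variant_ids) -> "VariantCounts":
        ids = pd.Index(variant_ids, name="variant_id")
        info = self.info.set_index("variant_id").loc[ids].reset_index()
        return VariantCounts(info, self.alt.loc[ids], self.depth.loc[ids])

    def select_samples(self, samples) -> "VariantCounts":
        return VariantCounts(self.info.copy(), self.alt[list(samples)], self.depth[list(samples)])


def validate_metadata(metadata: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    if not metadata["sample_id"].is_unique:
        raise ValueError("sample_id must be unique")


@dataclass
class FissionNode:
    """One clone in a crypt fission tree; the branch is the edge above it."""

    node_id: int
    parent: int | None
    start_age: float
    end_age: float
    children: list[int] = field(default_factory=list)
    crypts: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end_age - self.start_age

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class FissionTree:
    """Rooted binary fission history of one patient's crypts.

    Ages run forward from the patient's birth (0) to the sampling age;
    each internal node ends at its fission, each leaf at sampling.
    """

    nodes: dict[int, FissionNode]
    root: int
    sampling_age: float

    def leaves(self) -> list[FissionNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def branches(self) -> list[FissionNode]:
        """All nodes (each carries the branch above it), root first."""
        order, stack = [], [self.root]
        while stack:
            nid = stack.pop()
            order.append(self.nodes[nid])
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def clade(self, node_id: int) -> frozenset:
        return frozenset(self.nodes[node_id].crypts)

    def to_newick(self, lengths: dict[int, float] | None = None) -> str:
        """Newick string; branch lengths default to branch durations (years)."""

        def rec(nid: int) -> str:
            node = self.nodes[nid]
            length = lengths[nid] if lengths is not None else node.duration
            if node.is_leaf:
                return f"{node.crypts[0]}:{length:g}"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}):{length:g}"

        return rec(self.root) + ";"
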