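"""Node atlas for 85-region whole-brain structural connectomes.

The canonical parcellation is the 68-region Desikan-Killiany cortical
atlas plus 16 subcortical grey matter structures and the brainstem.
Node order is frozen in a packaged table (34 left cortical, 34 right
cortical, 8 left subcortical, 8 right subcortical, brainstem last) and
every matrix in the package is indexed against it. Indices are 0-based
everywhere, in files as well as APIs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

N_NODES = 85
N_PAIRS = N_NODES * (N_NODES - 1) // 2  # 3570 possible edges

HEMISPHERES = ("left", "right", "midline")
LOBES = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "cingulate",
    "insula",
    "subcortical",
    "brainstem",
)


@dataclass(frozen=True)
class AtlasNode:
    index: int
    name: str
    hemisphere: str
    lobe: str
    pair_index: int | None  # shared by left/right homologues; None for midline


@dataclass(frozen=True)
class Atlas:
    """Frozen node table defining canonical node order.

    ``bilateral_pairs`` lists the 42 (left-index, right-index) homologue
    pairs; the brainstem is the single unpaired midline node.
    """

    nodes: tuple[AtlasNode, ...]
    bilateral_pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.nodes) != N_NODES:
            raise ValueError(f"atlas must have {N_NODES} nodes, got {len(self.nodes)}")
        names = [n.name for n in self.nodes]
        if len(set(names)) != N_NODES:
            raise ValueError("node names must be unique")
        midline = [n for n in self.nodes if n.hemisphere == "midline"]
        if len(midline) != 1:
            raise ValueError("exactly one midline node expected")
        pairs: dict[int, dict[str, int]] = {}
        for n in self.nodes:
            if n.hemisphere == "midline":
                continue
            if n.pair_index is None:
                raise ValueError(f"non-midline node {n.name} lacks a pair index")
            pairs.setdefault(n.pair_index, {})[n.hemisphere] = n.index
        bilateral = []
        for k in sorted(pairs):
            sides = pairs[k]
            if set(sides) != {"left", "right"}:
                raise ValueError(f"pair {k} is not a left/right homologue pair")
            bilateral.append((sides["left"], sides["right"]))
        if len(bilateral) != 42:
            raise ValueError(f"expected 42 bilateral pairs, got {len(bilateral)}")
        object.__setattr__(self, "bilateral_pairs", tuple(bilateral))

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def hemispheres(self) -> list[str]:
        return [n.hemisphere for n in self.nodes]

    @property
    def lobes(self) -> list[str]:
        return [n.lobe for n in self.nodes]

    @property
    def midline_index(self) -> int:
        return next(n.index for n in self.nodes if n.hemisphere == "midline")

    def cortical_indices(self) -> list[int]:
        """Indices of the 68 cortical nodes (everything except subcortical/brainstem)."""
        return [
            n.index for n in self.nodes if n.lobe not in ("subcortical", "brainstem")
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [n.index for n in self.nodes],
                "name": self.names,
                "hemisphere": self.hemispheres,
                "lobe": self.lobes,
                "pair_index": [n.pair_index for n in self.nodes],
            }
        )


def _atlas_from_frame(df: pd.DataFrame) -> Atlas:
    required = {"index", "name", "hemisphere", "lobe", "pair_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    df = df.sort_values("index").reset_index(drop=True)
    if list(df["index"]) != list(range(len(df))):
        raise ValueError("atlas indices must be 0..84 without gaps")
    nodes = []
    for row in df.itertuples(index=False):
        hemi = str(row.hemisphere)
        if hemi not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemi!r}")
        lobe = str(row.lobe)
        if lobe not in LOBES:
            raise ValueError(f"unknown lobe {lobe!r}")
        pair = row.pair_index
        pair_index = None if pd.isna(pair) else int(pair)
        nodes.append(AtlasNode(int(row.index), str(row.name), hemi, lobe, pair_index))
    return Atlas(tuple(nodes))


def load_atlas(path: str | None = None) -> Atlas:
    """Load an atlas table; with no path, the packaged 85-region table."""
    if path is None:
        ref = importlib.resources.files("netcog.data").joinpath("atlas_dk85.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return _atlas_from_frame(df)


_DEFAULT_ATLAS: Atlas | None = None


def default_atlas() -> Atlas:
    """The packaged atlas, cached after first load."""
    global _DEFAULT_ATLAS
    if _DEFAULT_ATLAS is None:
        _DEFAULT_ATLAS = load_atlas()
    return _DEFAULT_ATLAS
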