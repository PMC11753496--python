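"""Per-residue B-factor normalization, averaging, differencing and rescaling.

Crystallographic B-factors from structures refined at different resolutions
are not directly comparable: the overall B offset and spread are dataset
properties.  Z-scoring the per-residue mean B within each structure removes
those, after which maps can be averaged across independent structures of the
same variant and differenced between variants to localise changes in
flexibility or disorder.  Residue identity is (chain, author residue number,
insertion code); maps from structures sharing a numbering scheme align
without any sequence alignment.  Residues missing from any input (unmodelled
density) are dropped by intersection and reported, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError

ResidueKey = tuple  # (chain: str, resseq: int, icode: str)

LINEAGES = ("raw", "znorm", "mean_relative", "averaged", "diff_signed",
            "diff_abs", "minmax01")


@dataclass
class ResidueBMap:
    """Ordered map (chain, resseq, icode) -> per-residue B statistic.

    ``lineage`` records the processing stage; ``sources`` the structure
    identifiers the values derive from; ``dropped`` lists residue keys
    removed by intersection operations.
    """

    values: dict
    lineage: str = "raw"
    sources: tuple = ()
    dropped: tuple = ()

    def __post_init__(self):
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")

    def __len__(self) -> int:
        return len(self.values)

    def array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def keys(self):
        return self.values.keys()


def znorm(bmap: ResidueBMap) -> ResidueBMap:
    """Z-score a raw map: value' = (value - mean) / sample SD (ddof=1)."""
    if len(bmap) < 3:
        raise InsufficientDataError(f"need >= 3 residues to z-normalize, got {len(bmap)}")
    vals = bmap.array()
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant B-factors: SD = 0")
    mean = vals.mean()
    out = {k: (v - mean) / sd for k, v in bmap.values.items()}
    return replace(bmap, values=out, lineage="znorm")


def mean_relative(bmap: ResidueBMap) -> ResidueBMap:
    """Alternative normalization: value' = value / mean (removes the offset
    scale but not the spread)."""
    vals = bmap.array()
    mean = vals.mean()
    if mean == 0:
        raise DegenerateInputError("zero mean B")
    out = {k: v / mean for k, v in bmap.values.items()}
    return replace(bmap, values=out, lineage="mean_relative")


def average_maps(maps: list[ResidueBMap]) -> ResidueBMap:
    """Per-residue mean over >= 2 normalized maps, restricted to residues
    present in every map; dropped residues are reported on the result."""
    if len(maps) < 2:
        raise InsufficientDataError("need >= 2 maps to average")
    common = set(maps[0].values)
    union = set(maps[0].values)
    for m in maps[1:]:
        common &= set(m.values)
        union |= set(m.values)
    if not common:
        raise DegenerateInputError("no residues common to all maps")
    dropped = tuple(sorted(union - common))
    out = {k: float(np.mean([m.values[k] for m in maps])) for k in sorted(common)}
    sources = tuple(s for m in maps for s in m.sources)
    return ResidueBMap(values=out, lineage="averaged", sources=sources, dropped=dropped)


def diff_maps(a: ResidueBMap, b: ResidueBMap, mode: str = "signed") -> ResidueBMap:
    """Residue-wise a - b (signed) or |a - b| (absolute) on the key
    intersection; both maps must be at the same lineage stage."""
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    if a.lineage != b.lineage:
        raise ValueError(f"lineage mismatch: {a.lineage!r} vs {b.lineage!r}")
    common = sorted(set(a.values) & set(b.values))
    if not common:
        raise DegenerateInputError("no residues common to both maps")
    dropped = tuple(sorted((set(a.values) | set(b.values)) - set(common)))
    if mode == "signed":
        out = {k: a.values[k] - b.values[k] for k in common}
        lineage = "diff_signed"
    else:
        out = {k: abs(a.values[k] - b.values[k]) for k in common}
        lineage = "diff_abs"
    return ResidueBMap(values=out, lineage=lineage,
                       sources=a.sources + b.sources, dropped=dropped)


def minmax01(bmap: ResidueBMap) -> ResidueBMap:
    """Rescale to [0, 1]: value' = (value - min) / (max - min)."""
    vals = bmap.array()
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateInputError("all values equal: min-max rescale undefined")
    out = {k: (v - lo) / (hi - lo) for k, v in bmap.values.items()}
    return replace(bmap, values=out, lineage="minmax01")


def write_bfactor_column(structure_path, bmap: ResidueBMap, out_path) -> dict:
    """Write ``bmap`` values into the B column of a copy of the structure.

    Every atom of a mapped residue receives the residue value (PDB fixed
    format, two decimals); atoms of unmapped residues get 0.00.  Returns a
    report dict listing unmapped residues and map keys that did not resolve.
    """
    import gemmi

    structure = gemmi.read_pdb(str(structure_path))
    model = structure[0]
    seen: set = set()
    unmapped: list = []
    for chain in model:
        for residue in chain:
            key = (chain.name, residue.seqid.num, residue.seqid.icode.strip() or "")
            value = bmap.values.get(key)
            if value is None:
                unmapped.append(key)
                value = 0.0
            else:
                seen.add(key)
            for atom in residue:
                atom.b_iso = float(value)
    unresolved = sorted(set(bmap.values) - seen)
    structure.write_pdb(str(out_path))
    return {"unmapped_residues": sorted(set(unmapped)), "unresolved_keys": unresolved}
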