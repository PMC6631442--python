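"""Vertical ionization potentials (vIP) of nucleobases and base-stack motifs.

The vIP of a molecule is the energy (eV) needed to remove one electron at
fixed geometry.  Along stacked DNA bases an electron hole migrates and
localizes preferentially at low-vIP sites, which is why per-motif vIP
tables are the central covariate of this package.  Single-base values
default to the experimental ones; stack vIPs (doublets to quadruplets)
are inputs loaded from TSV or XLSX tables, and longer motifs are composed
as the mean of their overlapping quadruplet windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._encoding import BASES, all_motifs, motif_to_code

__all__ = [
    "BaseVIPTable",
    "StackVIPTable",
    "builtin_base_vips",
    "load_stack_table",
    "motif_vip",
    "additive_vip",
    "delta_vip",
]

#: Experimental single-base vIPs in eV (gas phase): Gua < Ade < Cyt < Thy.
EXPERIMENTAL_BASE_VIPS = {"G": 8.20, "A": 8.42, "C": 8.85, "T": 9.10}

_VIP_RANGE = (5.0, 15.0)


def _check_motif(motif: str) -> None:
    if not motif:
        raise ValueError("empty motif")
    bad = set(motif) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT base(s) {sorted(bad)} in motif {motif!r}")


@dataclass(frozen=True)
class BaseVIPTable:
    """vIP (eV) of the four isolated nucleobases."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(BASES):
            raise ValueError(
                f"base table must have exactly A,C,G,T; got {sorted(self.values)}"
            )
        for b, v in self.values.items():
            if not (_VIP_RANGE[0] < float(v) < _VIP_RANGE[1]):
                raise ValueError(f"vIP({b})={v} eV outside plausible range {_VIP_RANGE}")

    def vip(self, base: str) -> float:
        try:
            return float(self.values[base])
        except KeyError:
            raise ValueError(f"base {base!r} not in {{A,C,G,T}}") from None

    def as_array(self) -> np.ndarray:
        """vIPs indexed by base code (A,C,G,T order)."""
        return np.array([self.values[b] for b in BASES], dtype=float)


def builtin_base_vips() -> BaseVIPTable:
    """Experimental single-base vIPs (eV): G=8.20, A=8.42, C=8.85, T=9.10."""
    return BaseVIPTable(dict(EXPERIMENTAL_BASE_VIPS))


@dataclass
class StackVIPTable:
    """vIPs (eV) of base-stack motifs of length 1-4.

    ``values`` maps an uppercase ACGT motif to its vIP.  ``complete_lengths``
    records the lengths at which the table claims to hold all 4**k motifs.
    """

    values: dict[str, float]
    source_label: str = ""
    complete_lengths: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for motif, v in self.values.items():
            _check_motif(motif)
            if motif != motif.upper():
                raise ValueError(f"motif {motif!r} not uppercase")
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric vIP {v!r} for motif {motif!r}") from None
        for k in self.complete_lengths:
            self._check_complete(k)

    def _check_complete(self, k: int) -> None:
        have = {m for m in self.values if len(m) == k}
        missing = sorted(set(all_motifs(k)) - have)
        if missing:
            raise ValueError(
                f"table claims completeness at length {k} but is missing "
                f"{len(missing)} motif(s), first: {missing[0]}"
            )

    def lengths(self) -> set[int]:
        return {len(m) for m in self.values}

    def vip(self, motif: str) -> float:
        _check_motif(motif)
        try:
            return float(self.values[motif])
        except KeyError:
            raise KeyError(f"motif {motif!r} absent from vIP table") from None

    def as_array(self, k: int) -> np.ndarray:
        """vIPs indexed by packed motif code for length k (NaN = absent).

        For k=5,6 (and beyond) the array is composed as the mean of the
        vIPs of the overlapping quadruplet windows, vectorized over all
        4**k codes; requires a complete quadruplet table.
        """
        if k <= 4:
            out = np.full(4**k, np.nan)
            for m, v in self.values.items():
                if len(m) == k:
                    out[motif_to_code(m)] = v
            return out
        quad = self.as_array(4)
        if np.isnan(quad).any():
            raise ValueError("composing length-%d vIPs needs all 256 quadruplets" % k)
        codes = np.arange(4**k, dtype=np.int64)
        windows = []
        for start in range(k - 3):
            shift = 2 * (k - 4 - start)
            windows.append(quad[(codes >> shift) & (4**4 - 1)])
        return np.mean(windows, axis=0)


def load_stack_table(
    path: str | Path,
    expected_lengths: Iterable[int] | None = None,
    source_label: str | None = None,
) -> StackVIPTable:
    """Load a motif->vIP table from TSV (columns motif, vip_ev) or XLSX.

    The XLSX layout maps sheet names to motif lengths (sheet-Single,
    sheet-Doublet, sheet-Triplet, sheet-Quadruplet, sheet-Quintuplet);
    each sheet needs columns ``motif`` and ``vip_ev``.  Completeness is
    enforced for every length in ``expected_lengths``.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        frames = [df for df in sheets.values() if {"motif", "vip_ev"} <= set(df.columns)]
        if not frames:
            raise ValueError(f"no sheet with columns motif/vip_ev in {path}")
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if not {"motif", "vip_ev"} <= set(df.columns):
        raise ValueError(f"{path} lacks required columns 'motif' and 'vip_ev'")

    values: dict[str, float] = {}
    for motif, vip in zip(df["motif"], df["vip_ev"]):
        motif = str(motif).strip()
        _check_motif(motif)
        try:
            v = float(vip)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric vIP {vip!r} for motif {motif!r}") from None
        if not np.isfinite(v):
            raise ValueError(f"non-finite vIP for motif {motif!r}")
        values[motif] = v

    expected = frozenset(int(k) for k in expected_lengths) if expected_lengths else frozenset()
    return StackVIPTable(
        values=values,
        source_label=source_label if source_label is not None else str(path),
        complete_lengths=expected,
    )


def motif_vip(stack_table: StackVIPTable, motif: str) -> float:
    """vIP of a motif: direct lookup up to length 4, composed above.

    A quintuplet is the mean of its two overlapping quadruplet windows, a
    sextuplet the mean of its three; longer motifs generalize to the mean
    over all contiguous quadruplet windows.
    """
    _check_motif(motif)
    if len(motif) <= 4:
        return stack_table.vip(motif)
    windows = [motif[i : i + 4] for i in range(len(motif) - 3)]
    return float(np.mean([stack_table.vip(w) for w in windows]))


def additive_vip(base_table: BaseVIPTable, motif: str) -> float:
    """Composition-only vIP estimate: mean of the constituent base vIPs."""
    _check_motif(motif)
    return float(np.mean([base_table.vip(b) for b in motif]))


def delta_vip(
    base_table: BaseVIPTable, ref_base: str, alt_base: str, absolute: bool = False
) -> float:
    """Change in single-base vIP upon substitution: vIP(alt) - vIP(ref)."""
    d = base_table.vip(alt_base) - base_table.vip(ref_base)
    return abs(d) if absolute else d
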