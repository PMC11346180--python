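"""Spectrum-vs-synthetic-peptide correlation and target-decoy FDR.

Identifications of microbiota peptides are validated by comparing the
fragmentation spectrum observed in plasma/serum with the spectrum of
the chemically synthesized peptide: peaks of the two lists are paired
by greedy nearest-neighbor matching within an m/z tolerance and the
Pearson correlation of the aligned intensity vectors is reported (the
study accepts peptides at correlation >= 0.7).

The proprietary local-FDR classifier of the original validation
software is replaced by a transparent global target-decoy estimator:
FDR(t) = #decoys above t / #targets above t, monotonized into q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "PeakList",
    "PsmScoreRecord",
    "match_peaks",
    "spectrum_correlation",
    "target_decoy_fdr",
    "q_values",
    "read_mgf",
    "write_mgf",
    "DEFAULT_TOLERANCE",
]

#: default peak-matching tolerance (Th), high-resolution TOF/Orbitrap regime
DEFAULT_TOLERANCE = 0.05


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: strictly increasing m/z, intensities >= 0."""

    spectrum_id: str
    mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("m/z and intensity lengths differ")
        mz = np.asarray(self.mz)
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class PsmScoreRecord:
    spectrum_id: str
    peptide: str
    score: float
    is_decoy: bool


def match_peaks(
    a: PeakList, b: PeakList, tolerance: float = DEFAULT_TOLERANCE
) -> tuple[np.ndarray, np.ndarray]:
    """Align two peak lists into equal-length intensity vectors.

    Peaks are paired greedily by smallest m/z difference within
    ``tolerance`` (ties broken toward the lower-m/z partner); each
    unmatched peak contributes its intensity against a zero in the
    other vector.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not a.mz or not b.mz:
        raise ValueError("empty peak list")
    pairs = [
        (abs(ma - mb), ma, mb, i, j)
        for i, ma in enumerate(a.mz)
        for j, mb in enumerate(b.mz)
        if abs(ma - mb) <= tolerance
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _d, _ma, _mb, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    va: list[float] = []
    vb: list[float] = []
    for i, j in sorted(matched):
        va.append(a.intensity[i])
        vb.append(b.intensity[j])
    for i in range(len(a.mz)):
        if i not in used_a:
            va.append(a.intensity[i])
            vb.append(0.0)
    for j in range(len(b.mz)):
        if j not in used_b:
            va.append(0.0)
            vb.append(b.intensity[j])
    return np.asarray(va), np.asarray(vb)


def spectrum_correlation(
    a: PeakList, b: PeakList, tolerance: float = DEFAULT_TOLERANCE
) -> float:
    """Pearson correlation of the aligned intensity vectors; symmetric
    and invariant to uniform intensity scaling."""
    if len(a.mz) < 2 or len(b.mz) < 2:
        raise ValueError("both spectra need >= 2 peaks")
    va, vb = match_peaks(a, b, tolerance)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant intensity vector: correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def target_decoy_fdr(records: Sequence[PsmScoreRecord], threshold: float) -> float:
    """Global target-decoy FDR at a score threshold:
    (#decoys above) / (#targets above)."""
    n_target = sum(1 for r in records if not r.is_decoy and r.score >= threshold)
    n_decoy = sum(1 for r in records if r.is_decoy and r.score >= threshold)
    if n_target == 0:
        raise ValueError("no targets above threshold: FDR undefined")
    return n_decoy / n_target


def q_values(records: Sequence[PsmScoreRecord]) -> dict[str, float]:
    """Monotone q-values for the target records by sweeping thresholds
    from the best score downward and taking the running minimum FDR."""
    ordered = sorted(records, key=lambda r: -r.score)
    n_target = 0
    n_decoy = 0
    fdrs: list[tuple[str, float]] = []
    for r in ordered:
        if r.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
            fdrs.append((r.spectrum_id, n_decoy / n_target))
    out: dict[str, float] = {}
    running = np.inf
    for spectrum_id, fdr in reversed(fdrs):
        running = min(running, fdr)
        out[spectrum_id] = running
    return out


def read_mgf(path: str | Path) -> list[PeakList]:
    """Read peak lists from an MGF file (TITLE used as spectrum id)."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            order = np.argsort(spec["m/z array"], kind="stable")
            out.append(
                PeakList(
                    spectrum_id=str(spec["params"].get("title", "")),
                    mz=tuple(float(x) for x in spec["m/z array"][order]),
                    intensity=tuple(float(x) for x in spec["intensity array"][order]),
                )
            )
    return out


def write_mgf(spectra: Sequence[PeakList], path: str | Path) -> None:
    entries = [
        {
            "m/z array": np.asarray(s.mz),
            "intensity array": np.asarray(s.intensity),
            "params": {"title": s.spectrum_id},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")
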