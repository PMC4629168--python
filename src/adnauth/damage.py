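"""5'-end C-to-T substitution profiles.

Postmortem cytosine deamination in single-stranded overhangs converts C to U,
read as T after amplification, so ancient reads show an excess of C->T
mismatches that is highest at the 5'-most base and decays towards the read
centre. This module counts those mismatches per read position (position 1 =
first aligned 5' base, in read orientation) and turns them into frequencies.

Reverse-strand reads are walked from the right-hand edge of the alignment
with both bases complemented, so a reference G aligned to a read A on the
minus strand is counted as C->T like its plus-strand mirror image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .sam_io import AlignmentSet

DEFAULT_MAX_POS = 20


@dataclass
class DamageProfile:
    """Per-position C->T counts at the 5' end.

    ``ref_c_counts[i]`` is the number of reads whose (read-orientation)
    reference base at position i+1 is C; ``ct_counts[i]`` the subset that
    read T there. ``freq`` is their ratio, NaN where the denominator is 0.
    """

    positions: np.ndarray  # 1..P
    ref_c_counts: np.ndarray
    ct_counts: np.ndarray
    n_reads: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.ref_c_counts = np.asarray(self.ref_c_counts, dtype=np.int64)
        self.ct_counts = np.asarray(self.ct_counts, dtype=np.int64)
        if np.any(self.ct_counts > self.ref_c_counts):
            raise ValueError("ct_counts exceed ref_c_counts")
        if np.any(self.ct_counts < 0):
            raise ValueError("negative counts")

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.ct_counts / self.ref_c_counts
        return np.where(self.ref_c_counts > 0, f, np.nan)

    @property
    def max_pos(self) -> int:
        return int(self.positions[-1])


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_C, _T = 1, 3


def damage_matrices(aset: AlignmentSet,
                    max_pos: int = DEFAULT_MAX_POS
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-read position-wise indicator matrices (n_reads x max_pos).

    Row r of the first matrix marks positions where read r's reference base
    (read orientation) is C; the second marks where it is C and the read
    base is T. Summing rows over any subset of reads yields that subset's
    profile counts, which is what makes resampling thousands of subsamples
    cheap.
    """
    n = len(aset.reads)
    refc = np.zeros((n, max_pos), dtype=np.uint8)
    ct = np.zeros((n, max_pos), dtype=np.uint8)
    for i, read in enumerate(aset.reads):
        q, r = read.oriented_columns()
        m = min(len(q), max_pos)
        qa = _CODE[np.frombuffer(q[:m].encode(), dtype=np.uint8)]
        ra = _CODE[np.frombuffer(r[:m].encode(), dtype=np.uint8)]
        isc = (ra == _C) & (qa != 255)  # N on either side is not counted
        refc[i, :m] = isc
        ct[i, :m] = isc & (qa == _T)
    return refc, ct


def profile_from_matrices(refc: np.ndarray, ct: np.ndarray,
                          n_reads: int) -> DamageProfile:
    max_pos = refc.shape[-1]
    return DamageProfile(
        positions=np.arange(1, max_pos + 1),
        ref_c_counts=refc.sum(axis=0, dtype=np.int64) if refc.ndim == 2 else refc,
        ct_counts=ct.sum(axis=0, dtype=np.int64) if ct.ndim == 2 else ct,
        n_reads=n_reads,
    )


def substitution_profile(aset: AlignmentSet,
                         max_pos: int = DEFAULT_MAX_POS) -> DamageProfile:
    """Count C->T substitutions over the first ``max_pos`` 5' positions."""
    if max_pos < 2:
        raise ValueError("max_pos must be at least 2")
    refc, ct = damage_matrices(aset, max_pos)
    prof = profile_from_matrices(refc, ct, n_reads=len(aset.reads))
    if not np.any(prof.ref_c_counts > 0):
        warnings.warn("no reference C observed at any position; "
                      "all frequencies undefined", stacklevel=2)
    return prof


def write_profile(profile: DamageProfile, path: str) -> None:
    """TSV with columns position, ref_c_count, ct_count, frequency."""
    with open(path, "w") as fh:
        fh.write("position\tref_c_count\tct_count\tfrequency\n")
        freq = profile.freq
        for i in range(len(profile.positions)):
            f = "NA" if math.isnan(freq[i]) else repr(float(freq[i]))
            fh.write(f"{profile.positions[i]}\t{profile.ref_c_counts[i]}\t"
                     f"{profile.ct_counts[i]}\t{f}\n")


def read_profile(path: str) -> DamageProfile:
    """Read a profile written by :func:`write_profile`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    # n_reads is not stored in the TSV; counts are what the fit consumes
    return DamageProfile(
        positions=df["position"].to_numpy(),
        ref_c_counts=df["ref_c_count"].to_numpy(),
        ct_counts=df["ct_count"].to_numpy(),
        n_reads=0,
    )


def plot_profile(profile: DamageProfile, fit=None, path: str | None = None):
    """Plot frequency against 5' position, optionally with the fitted
    exponential decay overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(profile.positions, profile.freq, "o", color="firebrick",
            label="observed C→T frequency")
    if fit is not None:
        x = np.linspace(profile.positions[0], profile.positions[-1], 200)
        ax.plot(x, fit.amplitude * np.exp(-fit.rate * x), "-",
                color="black",
                label=f"fit (gof p = {fit.gof_p:.3g})")
    ax.set_xlabel("position from 5' end")
    ax.set_ylabel("C→T frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
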