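"""Seeded synthetic scan series with realistic radiation-decay structure.

The generator emits the same per-scan reflection tables the analysis consumes,
with a factorized damage model:

    I_hkl(D) = I0_hkl * exp(-ln2 * D / D_half) * exp(-2 * dB(D) * (1/(2 d))^2) * noise

i.e. a global exponential intensity decay (half-dose ``D_half``) times a
resolution-dependent Wilson-style fading with a linearly growing B-factor
increment dB = b_rate * D -- damage empirically hits the highest-resolution
shells first.  The two rates are independent knobs: measured decay series
show both an overall exponential intensity loss and a linear resolution-limit
decline, but no established functional link between them, so none is imposed.
On top of the reflections, the unit-cell volume inflates linearly (% per
10 MGy) and the heavy-atom Ueq grows exponentially.

Defaults reproduce the conditions of a baseline decay experiment on a small
nickel-complex hydrate crystal: 16 repeated scans of 0.63 MGy each, half-dose
4.4 MGy, resolution falling 1 Angstrom per 10 MGy from 0.6 Angstrom, 2% cell
expansion per 10 MGy, and 2% multiplicative intensity noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import gemmi
import numpy as np
import pandas as pd

from .decay_analysis import ScanRecord, ScanSeries, laue_unique_ids

__all__ = [
    "DecayGroundTruth",
    "PAPER_EXP1",
    "reflection_template_from_cell",
    "generate_series",
    "generate_intensity_series",
    "generate_resolution_series",
]


@dataclass(frozen=True)
class DecayGroundTruth:
    """Generative parameters of a synthetic decay series."""

    d_half_mgy: float = 4.4               # global intensity half-dose
    resolution_slope_a_per_10mgy: float = 1.0
    b_rate_a2_per_mgy: float = 0.8        # Wilson B increment per MGy
    cell_expansion_pct_per_10mgy: float = 2.0
    ueq0_a2: float = 0.012                # heavy-atom Ueq at zero dose
    ueq_rate_per_mgy: float = 0.05        # exponential Ueq growth rate
    noise_multiplicative: float = 0.02    # lognormal fractional scatter
    noise_additive_sigma: float = 0.0     # absolute Gaussian sigma on I
    dose_per_scan_mgy: float = 0.63
    n_scans: int = 16
    d0_a: float = 0.6                     # zero-dose resolution limit
    seed: int = 0

    def __post_init__(self):
        if self.n_scans < 2:
            raise ValueError("need at least 2 scans")
        for name in ("d_half_mgy", "dose_per_scan_mgy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("resolution_slope_a_per_10mgy", "b_rate_a2_per_mgy",
                     "cell_expansion_pct_per_10mgy", "ueq_rate_per_mgy",
                     "noise_multiplicative", "noise_additive_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def doses(self) -> np.ndarray:
        """Cumulative-dose ladder: scan s has absorbed s * dose_per_scan."""
        return self.dose_per_scan_mgy * np.arange(1, self.n_scans + 1)


#: Baseline-experiment conditions (16 scans x 0.63 MGy, D_half 4.4 MGy,
#: 1 A / 10 MGy resolution decay, 2% noise).
PAPER_EXP1 = DecayGroundTruth()


def reflection_template_from_cell(cell, d_min: float,
                                  seed: int = 0,
                                  point_group: str = "P 21",
                                  mean_intensity: float = 1000.0,
                                  wilson_b_a2: float = 1.5,
                                  multiplicity: int = 2) -> pd.DataFrame:
    """Enumerate unique reflections of a cell to ``d_min`` with base intensities.

    Lattice points are enumerated to the resolution limit, reduced to
    Laue-unique representatives, and assigned positive base intensities from a
    Wilson-like model: an exp(-2 B (1/(2d))^2) falloff times a unit-mean
    exponential variate (acentric intensity statistics).  ``multiplicity``
    sets how many observations of each unique reflection a scan will carry.

    ``cell`` is a (a, b, c, alpha, beta, gamma) tuple or a gemmi.UnitCell.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    ucell = cell if isinstance(cell, gemmi.UnitCell) else gemmi.UnitCell(*cell)
    hmax = int(np.ceil(ucell.a / d_min))
    kmax = int(np.ceil(ucell.b / d_min))
    lmax = int(np.ceil(ucell.c / d_min))
    hs, ks, ls = np.meshgrid(np.arange(-hmax, hmax + 1),
                             np.arange(-kmax, kmax + 1),
                             np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([hs.ravel(), ks.ravel(), ls.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    inv_d2 = np.array([ucell.calculate_1_d2(m) for m in hkl])
    d = 1.0 / np.sqrt(inv_d2)
    keep = d >= d_min
    hkl, d = hkl[keep], d[keep]
    if len(hkl) == 0:
        raise ValueError(f"no reflections: d_min={d_min} exceeds the cell limit")

    ids = laue_unique_ids(hkl, point_group)
    _, first = np.unique(ids, return_index=True)
    hkl, d = hkl[first], d[first]

    rng = np.random.default_rng(seed)
    stol2 = (0.5 / d) ** 2
    base = mean_intensity * np.exp(-2.0 * wilson_b_a2 * stol2) \
        * rng.exponential(1.0, size=len(d))
    base = np.maximum(base, 1e-3 * mean_intensity * np.exp(-2.0 * wilson_b_a2 * stol2))
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    return pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                         "d": d, "I0": base,
                         "multiplicity": multiplicity})


def generate_series(truth: DecayGroundTruth, template: pd.DataFrame,
                    cell_volume_a3: float = 1279.19,
                    require_merging: bool = True) -> ScanSeries:
    """Synthesize a full decay series of reflection tables.

    Each scan repeats the template's unique reflections ``multiplicity`` times
    with the dose-dependent decay applied and seeded lognormal (and optional
    additive Gaussian) noise; cell volume and Ueq follow their stated laws.
    The ground truth is echoed in ``series.meta["truth"]``.
    """
    if require_merging and (template["multiplicity"] < 2).any():
        raise ValueError("merging statistics need multiplicity >= 2 per reflection")
    rng = np.random.default_rng(truth.seed)
    lam = np.log(2.0) / truth.d_half_mgy
    stol2 = (0.5 / template["d"].to_numpy()) ** 2
    scans = []
    for s, dose in enumerate(truth.doses(), start=1):
        db = truth.b_rate_a2_per_mgy * dose
        decay = np.exp(-lam * dose) * np.exp(-2.0 * db * stol2)
        rows = []
        for _ in range(int(template["multiplicity"].max())):
            mult_noise = rng.lognormal(mean=-0.5 * np.log(1 + truth.noise_multiplicative**2),
                                       sigma=np.sqrt(np.log(1 + truth.noise_multiplicative**2)),
                                       size=len(template))
            i_obs = template["I0"].to_numpy() * decay * mult_noise
            if truth.noise_additive_sigma > 0:
                i_obs = i_obs + rng.normal(0.0, truth.noise_additive_sigma,
                                           size=len(template))
            sig = np.sqrt((truth.noise_multiplicative * np.abs(i_obs)) ** 2
                          + truth.noise_additive_sigma**2) + 1e-9
            rows.append(pd.DataFrame({
                "h": template["h"], "k": template["k"], "l": template["l"],
                "d": template["d"], "I": i_obs, "sigI": sig,
            }))
        refl = pd.concat(rows, ignore_index=True)
        scans.append(ScanRecord(
            scan_id=s, dose_mgy=float(dose), reflections=refl,
            cell_volume=cell_volume_a3
            * (1.0 + truth.cell_expansion_pct_per_10mgy / 1000.0 * dose),
            ueq=truth.ueq0_a2 * np.exp(truth.ueq_rate_per_mgy * dose),
        ))
    return ScanSeries(scans=scans, meta={"truth": asdict(truth)})


def generate_intensity_series(truth: DecayGroundTruth,
                              seed: int | None = None) -> ScanSeries:
    """Summary-level series: normalized summed intensities with noise.

    I(D) = 100 exp(-ln2 D / D_half) times lognormal multiplicative noise --
    the direct generative model for half-dose recovery studies.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    doses = truth.doses()
    ideal = 100.0 * np.exp(-np.log(2.0) / truth.d_half_mgy * doses)
    frac = truth.noise_multiplicative
    noise = rng.lognormal(mean=-0.5 * np.log(1 + frac**2),
                          sigma=np.sqrt(np.log(1 + frac**2)), size=len(doses)) \
        if frac > 0 else np.ones(len(doses))
    frame = pd.DataFrame({"scan_id": np.arange(1, truth.n_scans + 1),
                          "dose": doses, "sumI": ideal * noise})
    return ScanSeries.from_summary_frame(frame)


def generate_resolution_series(truth: DecayGroundTruth,
                               seed: int | None = None,
                               noise_sigma_a: float = 0.02) -> pd.DataFrame:
    """Per-scan resolution limits following the linear decay law with noise.

    d_min(D) = d0 + (slope/10) * D + N(0, noise_sigma) -- the direct
    generative model for resolution-slope recovery studies.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    doses = truth.doses()
    dmin = truth.d0_a + truth.resolution_slope_a_per_10mgy / 10.0 * doses \
        + rng.normal(0.0, noise_sigma_a, size=len(doses))
    return pd.DataFrame({"scan_id": np.arange(1, truth.n_scans + 1),
                         "dose": doses, "dmin": dmin})
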