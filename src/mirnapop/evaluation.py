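"""Calibration experiments run on the synthetic generators.

These tie the statistics to their generating models: multi-locus Hudson
F_st should recover the Balding-Nichols differentiation parameter, and the
standardized iHS/nSL of a planted hard-sweep core should stand out of the
neutral score distribution.  The experiments are deterministic given their
seed and are reused by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .differentiation import hudson_fst_components, mean_fst
from .selection import scan, standardize
from .synthetic import SimConfig, SweepConfig, plant_sweep, \
    simulate_structured_haplotypes


def fst_recovery(F: float = 0.1, n_pops: int = 2, n_hap: int = 200,
                 n_sites: int = 2000, seed: int = 0,
                 method: str = "ratio_of_means") -> float:
    """Multi-locus Hudson F_st between the first two Balding-Nichols
    populations; with enough sites this recovers F."""
    cfg = SimConfig(seed=seed, n_pops=n_pops, n_hap=n_hap, n_sites=n_sites, F=F)
    mats, _truth = simulate_structured_haplotypes(cfg)
    pops = sorted(mats)
    f1 = mats[pops[0]].derived_freq()
    f2 = mats[pops[1]].derived_freq()
    N, D = hudson_fst_components(f1, n_hap, f2, n_hap)
    return mean_fst(N, D, method)


@dataclass
class SweepPowerResult:
    power: float
    n_replicates: int
    n_detected: int
    mean_core_z: float


def sweep_detection_power(n_replicates: int = 100, n_hap: int = 200,
                          n_sites: int = 500, carrier_fraction: float = 0.7,
                          spacing_bp: int = 100, block_bp: int = 20_000,
                          statistic: str = "iHS", n_bins: int = 50,
                          seed: int = 0,
                          neutral_quantile: float = 0.95) -> SweepPowerResult:
    """Fraction of replicates in which the planted core's |standardized
    score| exceeds the neutral quantile of |z|.

    Per replicate one single-population matrix is simulated, a hard sweep is
    planted at the central site, and scores are computed over all eligible
    cores.  Bin standardization is calibrated on the sites outside the swept
    block - the neutral-dominated reference a genome-wide scan provides,
    which the short simulated segment (40% of it swept) lacks - and the
    neutral |z| distribution is read off those same outside-block sites.
    """
    detected = 0
    core_zs = []
    for rep in range(n_replicates):
        rep_seed = seed + 10_000 + rep
        cfg = SimConfig(seed=rep_seed, n_pops=1, n_hap=n_hap,
                        n_sites=n_sites, spacing_bp=spacing_bp, F=0.1)
        mats, _ = simulate_structured_haplotypes(cfg)
        mat = mats["POP1"]
        core = n_sites // 2
        core_pos = int(mat.positions[core])
        mat = plant_sweep(mat, core, carrier_fraction, block_bp,
                          seed=rep_seed + 1)
        raw = scan(mat, statistic)
        pos_of = dict(zip(mat.site_ids, mat.positions))
        outside = [s for s in raw
                   if abs(int(pos_of[s.snp_id]) - core_pos) > block_bp // 2]
        scores = standardize(raw, n_bins, reference=outside)
        core_id = mat.site_ids[core]
        z_core = None
        neutral = []
        for s in scores:
            if s.snp_id == core_id:
                z_core = s.standardized
            elif abs(int(pos_of[s.snp_id]) - core_pos) > block_bp // 2:
                neutral.append(abs(s.standardized))
        if z_core is None or not neutral:
            continue
        core_zs.append(abs(z_core))
        if abs(z_core) > float(np.quantile(neutral, neutral_quantile)):
            detected += 1
    return SweepPowerResult(power=detected / n_replicates,
                            n_replicates=n_replicates, n_detected=detected,
                            mean_core_z=float(np.mean(core_zs)) if core_zs else 0.0)
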