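"""Batch driver: generate/analyze many nuclei and tidy the results."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .spatial_stats import NucleusAnalysis, RadialProfile, analyze_volume
from .synthetic import SyntheticParams, generate_nucleus_volume

__all__ = ["run_condition_batch", "analyses_to_tables"]


def run_condition_batch(
    params: SyntheticParams,
    n_nuclei: int,
    seed: int,
    **analyze_kwargs,
) -> tuple[list[RadialProfile], list[NucleusAnalysis]]:
    """Generate and analyze ``n_nuclei`` synthetic nuclei for one condition.

    Each nucleus gets its own sub-seed derived from ``seed`` so batches are
    reproducible yet nuclei are independent.  Returns the pooled normalized
    profiles (telomere = unit of replication) and the per-nucleus analyses.
    """
    profiles: list[RadialProfile] = []
    analyses: list[NucleusAnalysis] = []
    for i in range(n_nuclei):
        p = dataclasses.replace(params, seed=(seed + 7919 * i) % (2**31))
        volume, _ = generate_nucleus_volume(p)
        result = analyze_volume(volume, nucleus_id=i, **analyze_kwargs)
        profiles.extend(result.profiles)
        analyses.append(result)
    return profiles, analyses


def analyses_to_tables(
    analyses: Sequence[NucleusAnalysis], condition: str = "default"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten per-nucleus analyses into telomere- and nucleus-level tables."""
    tel_rows, nuc_rows = [], []
    for res in analyses:
        dist = {d.telomere_id: d for d in res.distance_records}
        for rec in res.coverage_records:
            d = dist.get(rec.telomere_id)
            tel_rows.append({
                "condition": condition,
                "nucleus_id": res.nucleus_id,
                "telomere_id": rec.telomere_id,
                "coverage_percent": rec.coverage_percent,
                "category": rec.category,
                "distance_nm": d.distance_nm if d else float("nan"),
                "within_threshold": d.within_threshold if d else False,
            })
        nuc_rows.append({
            "condition": condition,
            "nucleus_id": res.nucleus_id,
            "lap2c_percent": res.coverage_stats.lap2c_percent,
            "sigma_percent": res.coverage_stats.sigma_percent,
            "n_telomeres": res.coverage_stats.n_telomeres,
        })
    return pd.DataFrame(tel_rows), pd.DataFrame(nuc_rows)
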