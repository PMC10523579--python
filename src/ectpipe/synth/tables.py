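"""Synthetic concentration–response and qPCR Ct tables.

Both tables are built so the downstream analysis recovers the programmed
quantities exactly in the noiseless limit: responses lie on the 4PL curve,
and Ct values are constructed from programmed relative quantities (RQ)
around shared reference genes, so that 2^(−ΔΔCt) returns the RQs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..models import four_pl
from .groundtruth import GroundTruth

__all__ = ["gen_dose_response", "gen_ct_table"]


def gen_dose_response(
    fit: Mapping[str, float],
    concentrations: Sequence[float],
    cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Concentration–response table sampled from a 4PL curve.

    ``fit`` holds ``bottom``, ``top``, ``ec50``, ``hill``.  Each response is
    the curve value times a multiplicative Gaussian factor ``1 + cv*N(0,1)``
    (``cv=0`` gives exact curve values).  Returns a long table with columns
    ``concentration``, ``response``, ``replicate``.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    mu = four_pl(conc, fit["bottom"], fit["top"], fit["ec50"], fit["hill"])
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        y = mu * (1.0 + cv * rng.standard_normal(conc.size)) if cv > 0 else mu.copy()
        rows.append(
            pd.DataFrame(
                {"concentration": conc, "response": y, "replicate": rep}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    gt = GroundTruth(
        "dose_response",
        {"fit": dict(fit), "concentrations": conc, "cv": cv, "replicates": replicates},
        seed,
    )
    return table, gt


def gen_ct_table(
    true_rqs: Mapping[str, Mapping[str, float]],
    ref_genes: Sequence[str] = ("GAPDH", "RPL13A"),
    calibrator: str | None = None,
    n_samples: int = 6,
    noise_sd: float = 0.0,
    duplicates: int = 2,
    ref_ct: float = 20.0,
    target_base_ct: float = 26.0,
    loading_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table consistent with programmed relative quantities.

    ``true_rqs`` maps gene → {group → RQ vs. the calibrator group}; the
    calibrator (default: first group seen) must have RQ 1 for every gene.
    Each sample gets a loading offset (sd ``loading_sd`` cycles) applied to
    all its wells — it cancels in ΔCt.  Reference genes sit near ``ref_ct``;
    target genes near ``target_base_ct`` shifted by ``−log2(RQ)``.
    Per-well replicate noise has sd ``noise_sd`` cycles; with ``noise_sd=0``
    the programmed RQs are recovered exactly by ΔΔCt analysis.
    """
    genes = list(true_rqs)
    groups = list(next(iter(true_rqs.values())))
    if calibrator is None:
        calibrator = groups[0]
    for g, per_group in true_rqs.items():
        if set(per_group) != set(groups):
            raise ValueError("every gene needs an RQ for every group")
        if not np.isclose(per_group[calibrator], 1.0):
            raise ValueError(f"calibrator RQ must be 1 (gene {g})")
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        for s in range(1, n_samples + 1):
            sample = f"{group}_{s}"
            load = rng.normal(0.0, loading_sd) if loading_sd > 0 else 0.0
            cts = {ref: ref_ct + load for ref in ref_genes}
            for gene in genes:
                cts[gene] = (
                    target_base_ct - np.log2(true_rqs[gene][group]) + load
                )
            for gene, ct in cts.items():
                for rep in range(1, duplicates + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep,
                            "ct": ct + noise,
                        }
                    )
    table = pd.DataFrame(rows)
    gt = GroundTruth(
        "ct_table",
        {
            "true_rqs": {g: dict(v) for g, v in true_rqs.items()},
            "ref_genes": list(ref_genes),
            "calibrator": calibrator,
            "n_samples": n_samples,
            "noise_sd": noise_sd,
            "duplicates": duplicates,
        },
        seed,
    )
    return table, gt
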