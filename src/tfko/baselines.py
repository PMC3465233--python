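"""Random-removal baseline and comparison harness.

The refined collection removes the ~10% of targets with no regulatory
path.  To show that this beats chance, each baseline replicate removes the
same fraction *at random* from every TF's original list; the refined
collection is then compared against every replicate with the three
validation measures, counting per measure how many TFs each side wins.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping, Sequence, Set as AbstractSet
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import ValidationResources, validate_collection

__all__ = ["RandomBaseline", "random_removal", "compare_to_baselines"]


@dataclass(frozen=True)
class RandomBaseline:
    """One random-removal replicate over a TF -> target-set collection."""

    replicate_index: int
    removed_fraction: float
    seed: int
    sets: Mapping[str, frozenset[str]]


def _rng_for(seed: int, replicate: int, tf: str) -> np.random.Generator:
    # Counter scheme: (master seed, replicate index, CRC32 of the TF name)
    # seeds an independent stream per (TF, replicate), so adding or removing
    # TFs never perturbs the draws of the others.
    return np.random.default_rng(
        np.random.SeedSequence([seed, replicate, zlib.crc32(tf.encode())])
    )


def random_removal(
    original: Mapping[str, AbstractSet[str]],
    fraction: float = 0.1,
    n_replicates: int = 10,
    seed: int = 0,
) -> list[RandomBaseline]:
    """Remove ``floor(fraction * n)`` targets uniformly at random (without
    replacement) from each TF's list, independently per TF and replicate.

    Fully reproducible from the master seed.  Sets too small for the floor
    to reach 1 are returned unchanged.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"removal fraction must lie in (0, 1), got {fraction}")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    baselines = []
    for rep in range(n_replicates):
        sets: dict[str, frozenset[str]] = {}
        for tf in sorted(original):
            genes = sorted(original[tf])
            n_remove = int(np.floor(fraction * len(genes)))
            rng = _rng_for(seed, rep, tf)
            removed = set(
                rng.choice(len(genes), size=n_remove, replace=False).tolist()
            )
            sets[tf] = frozenset(
                g for i, g in enumerate(genes) if i not in removed
            )
        baselines.append(
            RandomBaseline(
                replicate_index=rep, removed_fraction=fraction, seed=seed, sets=sets
            )
        )
    return baselines


def compare_to_baselines(
    refined: Mapping[str, AbstractSet[str]],
    baselines: Sequence[RandomBaseline],
    resources: ValidationResources,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Validate the refined collection against every baseline replicate.

    Returns one row per replicate with, for each measure, the number of
    TFs won by the refined side and by the baseline side:

    * enrichment — strictly higher enrichment score;
    * coherence — significantly higher coherence (one-sided rank-sum,
      BH across TFs);
    * PPI — strictly smaller module-membership p-value, with the counts of
      module-enriched TFs per side also reported.

    ``refined_wins_all`` flags replicates where the refined side wins every
    measure's count comparison.
    """
    rows = []
    for baseline in baselines:
        report = validate_collection(
            refined,
            baseline.sets,
            resources,
            fdr=fdr,
            label_a="refined",
            label_b=f"random_{baseline.replicate_index}",
        )
        s = report.summary
        enrich_ref, enrich_base = s["enrichment_a_gt_b"], s["enrichment_b_gt_a"]
        coh_ref, coh_base = s["coherence_sig_a"], s["coherence_sig_b"]
        ppi_ref, ppi_base = s["ppi_smaller_p_a"], s["ppi_smaller_p_b"]
        rows.append(
            {
                "replicate": baseline.replicate_index,
                "removed_fraction": baseline.removed_fraction,
                "enrichment_wins_refined": enrich_ref,
                "enrichment_wins_baseline": enrich_base,
                "coherence_wins_refined": coh_ref,
                "coherence_wins_baseline": coh_base,
                "ppi_wins_refined": ppi_ref,
                "ppi_wins_baseline": ppi_base,
                "ppi_enriched_refined": s["ppi_enriched_a"],
                "ppi_enriched_baseline": s["ppi_enriched_b"],
                "refined_wins_all": bool(
                    enrich_ref > enrich_base
                    and coh_ref > coh_base
                    and ppi_ref > ppi_base
                ),
            }
        )
    return pd.DataFrame(rows)
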