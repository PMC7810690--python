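"""End-to-end orchestration: simulate/annotate → overlap → neighbors → null.

The pipeline is a thin composition of the library stages.  Every output
file carries a header with the package version, the seed and the stage
parameters; reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .annotator import annotate_fasta
from .errors import InvalidInputError
from .neighborhood import count_pairs, normalize, pairwise_r2
from .null_model import null_frequencies
from .overlapper import (build_contigs, filter_marker_concordant,
                         find_overlaps, fingerprint_from_units)
from .synthetic import SimConfig, emit_fasta, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run (validated by each stage's contract)."""

    out_dir: str | Path
    seed: int = 0
    sim: SimConfig | None = None          # simulate when set ...
    assemblies_fasta: str | Path | None = None  # ... else annotate this FASTA
    tolerance: int = 35
    min_n: int = 2
    max_n: int = 30
    try_flip: bool = True
    marker_concordance: bool = True
    strict_contigs: bool = False  # skip, rather than fail on, conflicting matches
    offsets: tuple[int, ...] = (1, 2, 3)
    mode: str = "feature_code"
    replicates: int = 1000
    retain_above: float = 0.90
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and self.assemblies_fasta is None:
            raise InvalidInputError("need either a SimConfig or an assemblies FASTA")


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run the requested stages; returns the summary written to summary.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, object] = {"seed": config.seed}

    if config.sim is not None:
        sim = SimConfig(**{**sim_as_dict(config.sim), "seed": config.seed})
        truth = simulate_dataset(sim)
        fasta = out / "assemblies.fasta"
        emit_fasta(truth, fasta)
        logger.info("simulated %d BACs over a %d-unit array", sim.n_bacs, sim.n_units)
        summary["n_bacs_simulated"] = len(truth.windows)
    else:
        fasta = Path(config.assemblies_fasta)

    units_by_assembly = annotate_fasta(fasta)
    io.write_unit_catalog_tsv(units_by_assembly, out / "catalog.tsv",
                              params=f"seed={config.seed}")
    catalog = io.catalog_from_units(units_by_assembly)
    io.write_legacy_catalog(catalog, out / "catalog_legacy.txt")
    summary["n_assemblies"] = len(units_by_assembly)
    summary["n_units_annotated"] = sum(len(v) for v in catalog.values())

    fps = [fingerprint_from_units([u for u in units if not (u.partial or u.unclassifiable)])
           for units in units_by_assembly.values()]
    matches = []
    for fa, fb in itertools.combinations(fps, 2):
        matches.extend(find_overlaps(fa, fb, tolerance=config.tolerance,
                                     min_n=config.min_n, max_n=config.max_n,
                                     try_flip=config.try_flip))
    if config.marker_concordance:
        matches = filter_marker_concordant(matches, catalog)
    params = (f"tolerance={config.tolerance} min_n={config.min_n} "
              f"max_n={config.max_n} flip={config.try_flip}")
    io.write_matches(matches, out / "matches.tsv", params=params)
    io.write_dot(matches, out / "overlaps.dot")
    contigs = build_contigs(fps, matches, strict=config.strict_contigs)
    io.write_contigs(contigs, out / "contigs.tsv", params=params)
    summary["n_matches"] = len(matches)
    summary["n_contigs"] = len(contigs)
    summary["n_multi_member_contigs"] = sum(1 for c in contigs if c.n_members > 1)
    summary["longest_contig_bp"] = max((c.total_length_bp for c in contigs), default=0)

    matrices = {}
    for k in config.offsets:
        pcm = normalize(count_pairs(catalog, k, mode=config.mode))
        matrices[k] = pcm
        io.write_pair_matrix(pcm, out / f"pairs_k{k}.tsv",
                             params=f"offset k={k} mode={config.mode}")
        if config.make_plots:
            from .plotting import save_heatmap
            save_heatmap(pcm, out / f"pairs_k{k}.png")
    ensemble = null_frequencies(catalog, config.offsets[0],
                                replicates=config.replicates, seed=config.seed,
                                retain_above=config.retain_above, mode=config.mode)
    io.write_ensemble(ensemble, out / f"null_k{config.offsets[0]}.tsv")
    summary["n_pairs_retained_null"] = len(ensemble.retained)
    if len(config.offsets) >= 2:
        k1, k2 = config.offsets[0], config.offsets[1]
        summary[f"r2_k{k1}_k{k2}"] = pairwise_r2(matrices[k1].normalized,
                                                 matrices[k2].normalized)
    summary[f"r2_k{config.offsets[0]}_null"] = pairwise_r2(
        matrices[config.offsets[0]].normalized, ensemble.normalized_null)

    io.write_run_summary(summary, out / "summary.json")
    return summary


def sim_as_dict(sim: SimConfig) -> dict:
    from dataclasses import asdict
    d = asdict(sim)
    d["type_freqs"] = dict(sim.type_freqs)
    d["sali_freqs"] = dict(sim.sali_freqs)
    return d
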