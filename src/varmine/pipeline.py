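"""Mining-cycle orchestration.

A *cycle* runs the full stage order on a repository — cleanse (filter) ->
profile -> hotspot/pattern mining -> protein-level analysis (when
annotations and binding sites are available) -> candidate selection —
writes every artifact to the cycle's output directory, and flags the top
``depth`` candidates as entries into the next cycle.

New-sequence acquisition per cycle is an injectable *sequence source*;
the bundled source draws fresh variants from the synthetic generator (the
study's per-cycle expansion by external homology search is simulated with
the same control flow, without any network dependency).  All stage
parameters are logged to ``params.json`` so every run is recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from . import __version__
from .filters import FilterReport, filter_repository
from .mining import (find_hotspots, find_patterns, hotspots_to_dataframe,
                     mismatch_matrix, patterns_to_dataframe)
from .profiling import RegionTable, call_mutations, composition, profiles_to_dataframe
from .protein import (AnnotationSet, BindingSiteConfig, map_substitutions,
                      proximity_scores, select_candidates)
from .records import Repository, SequenceRecord, translate, with_cycle, write_fasta
from .simulate import GeneratorSpec, generate_variants

DEFAULT_DEPTHS = (25, 25, 40, 25)


class SequenceSource(Protocol):
    """Supplies new candidate sequences for a mining cycle."""

    def draw(self, n: int, cycle: int) -> list[SequenceRecord]: ...


class GeneratorSource:
    """Sequence source backed by the synthetic variant generator."""

    def __init__(self, reference: SequenceRecord, spec: GeneratorSpec):
        self.reference = reference
        self.spec = spec
        self._counter = 0

    def draw(self, n: int, cycle: int) -> list[SequenceRecord]:
        spec = dc_replace(self.spec, n_variants=n,
                          seed=int(self.spec.seed + 7919 * (cycle + 1)))
        repo, _ = generate_variants(self.reference, spec)
        out = []
        for rec in repo.members:
            self._counter += 1
            out.append(SequenceRecord(id=f"c{cycle}_{self._counter:04d}",
                                      seq=rec.seq, kind=rec.kind,
                                      source="synthetic", cycle=cycle))
        return out


@dataclass
class CycleConfig:
    cycle_index: int
    depth: int = 25                        # entries carried into the next cycle
    out_dir: str | Path = "cycle_out"
    hi: float = 0.99                       # similarity filter thresholds
    lo: float = 0.75
    min_share: int = 4                     # hotspot support (inclusive)
    min_support: int = 5                   # pattern support (> 4)
    max_gap: int = 4
    max_span: int = 10
    line_len: int = 60
    substrate_window: int = 5
    nucleotide_window: int = 3
    regions: RegionTable | None = None
    annotations: AnnotationSet | None = None
    binding_sites: BindingSiteConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    def params_dict(self) -> dict:
        return {"cycle_index": self.cycle_index, "depth": self.depth,
                "hi": self.hi, "lo": self.lo, "min_share": self.min_share,
                "min_support": self.min_support, "max_gap": self.max_gap,
                "max_span": self.max_span, "line_len": self.line_len,
                "substrate_window": self.substrate_window,
                "nucleotide_window": self.nucleotide_window, "seed": self.seed,
                "protein_stage": self.binding_sites is not None,
                "varmine_version": __version__}


@dataclass
class CycleReport:
    cycle_index: int
    n_in: int
    n_kept: int
    n_removed: int
    filter_report: FilterReport
    hotspots: list
    patterns: list
    candidates: pd.DataFrame
    next_entries: list[str]
    manifest: dict[str, Path] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def run_cycle(repo: Repository, config: CycleConfig) -> CycleReport:
    """Run one full mining cycle and write all artifacts.

    Any stage failure raises with the stage name; artifacts written before
    the failure remain on disk as a partial manifest.
    """
    if not repo.members:
        raise ValueError("repository has no members")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    warnings: list[str] = []
    stage = "filter"
    try:
        filtered, freport = filter_repository(repo, hi=config.hi, lo=config.lo)
        p = out / "filter_report.tsv"
        freport.to_dataframe().to_csv(p, sep="\t", index=False)
        manifest["filter_report"] = p
        if filtered.members:
            p = out / "filtered.fasta"
            write_fasta([filtered.reference, *filtered.members], p)
            manifest["filtered_fasta"] = p

        stage = "profile"
        profiles = [call_mutations(filtered.reference, rec, regions=config.regions)
                    for rec in filtered.members]
        p = out / "profiles.tsv"
        profiles_to_dataframe(profiles).to_csv(p, sep="\t", index=False)
        manifest["profiles"] = p
        comp_rows = []
        for rec in [filtered.reference, *filtered.members]:
            c = composition(rec)
            comp_rows.append({"seq_id": rec.id, "A": c.a, "C": c.c, "G": c.g,
                              "T": c.t, "N": c.n,
                              "gc_percent": round(c.gc_percent, 3),
                              "at_percent": round(c.at_percent, 3)})
        p = out / "composition.tsv"
        pd.DataFrame(comp_rows).to_csv(p, sep="\t", index=False)
        manifest["composition"] = p

        stage = "mining"
        hotspots = find_hotspots(profiles, config.min_share) if profiles else []
        p = out / "hotspots.tsv"
        hotspots_to_dataframe(hotspots).to_csv(p, sep="\t", index=False)
        manifest["hotspots"] = p
        patterns = find_patterns(profiles, config.min_support, config.max_gap,
                                 config.max_span) if profiles else []
        p = out / "patterns.tsv"
        patterns_to_dataframe(patterns).to_csv(p, sep="\t", index=False)
        manifest["patterns"] = p
        p = out / "mismatch_matrix.csv"
        mismatch_matrix(profiles, config.line_len).to_csv(p)
        manifest["mismatch_matrix"] = p

        subs_by_seq = {}
        excluded: list[str] = []
        if config.binding_sites is not None and profiles:
            stage = "protein"
            ref_prot = translate(filtered.reference)
            for rec in filtered.members:
                if len(rec.seq) != len(filtered.reference.seq) or len(rec.seq) % 3:
                    warnings.append(f"{rec.id}: skipped protein stage "
                                    "(length differs from reference)")
                    continue
                subs_by_seq[rec.id] = map_substitutions(
                    ref_prot, translate(rec), config.annotations)
            subs_by_seq, penalty, excluded = proximity_scores(
                subs_by_seq, config.binding_sites,
                config.substrate_window, config.nucleotide_window)
            p = out / "penalty_matrix.csv"
            penalty.to_csv(p)
            manifest["penalty_matrix"] = p

        stage = "selection"
        if profiles:
            candidates = select_candidates(profiles, subs_by_seq, excluded, hotspots)
        else:
            candidates = pd.DataFrame(columns=["rank", "seq_id", "excluded",
                                               "n_adjacent", "hotspot_overlap",
                                               "identity", "n_mutations",
                                               "region_group"])
            warnings.append("no sequences survived filtering")
        p = out / "candidates.tsv"
        candidates.to_csv(p, sep="\t", index=False)
        manifest["candidates"] = p

        eligible = candidates[~candidates["excluded"]] if len(candidates) else candidates
        next_entries = eligible["seq_id"].head(config.depth).tolist()
        if len(next_entries) < config.depth:
            warnings.append(f"depth {config.depth} exceeds surviving sequences "
                            f"({len(next_entries)}); carrying all survivors")

        p = out / "params.json"
        p.write_text(json.dumps(config.params_dict(), indent=2, sort_keys=True) + "\n")
        manifest["params"] = p
        report = CycleReport(cycle_index=config.cycle_index, n_in=len(repo.members),
                             n_kept=len(filtered.members),
                             n_removed=len(freport.removed),
                             filter_report=freport, hotspots=hotspots,
                             patterns=patterns, candidates=candidates,
                             next_entries=next_entries, manifest=manifest,
                             warnings=warnings)
        p = out / "manifest.json"
        p.write_text(json.dumps(
            {"cycle": config.cycle_index,
             "files": {k: str(v) for k, v in manifest.items()},
             "counts": {"in": report.n_in, "kept": report.n_kept,
                        "removed": report.n_removed},
             "next_entries": next_entries, "warnings": warnings},
            indent=2, sort_keys=True) + "\n")
        report.manifest["manifest"] = p
        return report
    except Exception as exc:
        raise RuntimeError(
            f"cycle {config.cycle_index} failed at stage {stage!r}: {exc}"
        ) from exc


def run_pipeline(reference: SequenceRecord, source: SequenceSource,
                 out_dir: str | Path, depths: tuple[int, ...] = DEFAULT_DEPTHS,
                 n_new_per_cycle: int = 250, seed: int = 0,
                 config_factory: Callable[[int], CycleConfig] | None = None,
                 initial_members: list[SequenceRecord] | None = None
                 ) -> list[CycleReport]:
    """Run a multi-cycle mining pass (default depth schedule 25, 25, 40, 25).

    Each cycle mines the union of the previous cycle's carried entries and
    ``n_new_per_cycle`` fresh sequences from ``source``; ``initial_members``
    seed the first cycle alongside its fresh draw.
    """
    out_dir = Path(out_dir)
    carried: list[SequenceRecord] = list(initial_members or [])
    reports: list[CycleReport] = []
    for i, depth in enumerate(depths, start=1):
        fresh = [with_cycle(r, i) for r in source.draw(n_new_per_cycle, i)]
        members = carried + fresh
        repo = Repository(reference, members)
        if config_factory is not None:
            config = config_factory(i)
            config.cycle_index, config.depth = i, depth
            config.out_dir = out_dir / f"cycle{i}"
        else:
            config = CycleConfig(cycle_index=i, depth=depth,
                                 out_dir=out_dir / f"cycle{i}", seed=seed)
        report = run_cycle(repo, config)
        reports.append(report)
        keep = set(report.next_entries)
        carried = [m for m in members if m.id in keep]
    summary = {"depths": list(depths), "cycles": [
        {"cycle": r.cycle_index, "in": r.n_in, "kept": r.n_kept,
         "removed": r.n_removed, "carried": len(r.next_entries)} for r in reports]}
    (out_dir / "pipeline_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return reports
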