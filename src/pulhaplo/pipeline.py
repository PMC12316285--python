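"""End-to-end pipeline: simulate -> screen assemblies -> classify haplotypes
-> design probes -> screen reads -> cohort statistics, with a JSON manifest
recording seed, thresholds and per-stage outcomes."""

from __future__ import annotations

import hashlib
import json
import platform
from collections import defaultdict
from pulhaplo import __version__
from pulhaplo.config import PipelineConfig
from pulhaplo.groups import (
    GroupProfile,
    PULHaplotypeCall,
    assign_gene_group,
    call_haplotype,
    scan_breakpoint,
)
from pulhaplo.probes import Probe, call_sample, design_probes, dominant_group, match_reads
from pulhaplo.reference import GH16_GENE_ID, LocusReference, build_reference
from pulhaplo.screen import WHOLE_LOCUS_ID, LocusCall, screen_locus
from pulhaplo.simulate import Cohort, make_group_references, simulate_cohort


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def classify_sample(call: LocusCall, profiles: dict[str, GroupProfile], *,
                    identity_min: float = 80.0, tie_margin: float = 0.5,
                    window: int = 60, step: int = 3) -> PULHaplotypeCall | None:
    """Haplotype call for one screened sample (None when nothing was hit)."""
    hits = [h for h in call.hits if h.gene_id != WHOLE_LOCUS_ID]
    if not hits:
        return None
    per_contig = defaultdict(list)
    for h in hits:
        per_contig[h.contig_id].append(
            assign_gene_group(h.aligned_nt_seq, h.gene_id, profiles,
                              identity_min=identity_min, tie_margin=tie_margin))
    hap = call_haplotype(dict(per_contig), complete=call.complete,
                         sample_id=call.sample_id)
    if hap.recombinant:
        gh16_hits = [h for h in hits if h.gene_id == GH16_GENE_ID]
        if gh16_hits:
            seq = gh16_hits[0].aligned_nt_seq
            pa = "GIII" if "GIIIrec" in hap.groups else "GII"
            ref_a = profiles[pa].nt[GH16_GENE_ID]
            ref_b = profiles["GI"].nt[GH16_GENE_ID]
            if len(seq) == len(ref_a) == len(ref_b):
                intervals, multi = scan_breakpoint(seq, ref_a, ref_b,
                                                   window=window, step=step)
                if intervals:
                    hap.breakpoint_interval = intervals[0]
                    hap.multi_crossover = multi
    return hap


def screen_cohort(cohort: Cohort, locus: LocusReference,
                  pcfg: PipelineConfig, mode: str = "gene_strict"
                  ) -> dict[str, LocusCall]:
    return {
        s.sample_id: screen_locus(
            s.contigs, locus, mode, identity_min=pcfg.identity_min,
            coverage_min=pcfg.coverage_min, truncation_frac=pcfg.truncation_frac,
            sample_id=s.sample_id)
        for s in cohort.samples
    }


def classify_cohort(calls: dict[str, LocusCall],
                    profiles: dict[str, GroupProfile],
                    pcfg: PipelineConfig) -> dict[str, PULHaplotypeCall | None]:
    return {sid: classify_sample(c, profiles, identity_min=pcfg.identity_min,
                                 tie_margin=pcfg.tie_margin)
            for sid, c in calls.items()}


def read_screen_cohort(cohort: Cohort, probes: list[Probe],
                       pcfg: PipelineConfig) -> dict[str, "object"]:
    out = {}
    for s in cohort.samples:
        counts, total, skipped, multi = match_reads(cohort.reads_for(s), probes)
        out[s.sample_id] = call_sample(
            counts, total, min_reads=pcfg.min_reads,
            dom_threshold=pcfg.dom_threshold, sample_id=s.sample_id,
            n_skipped_short=skipped, n_multi_probe=multi)
    return out


def design_cohort_probes(refs: dict[str, LocusReference],
                         probe_len: int = 54) -> list[Probe]:
    gh16 = {g: r.gene(GH16_GENE_ID).nt_seq for g, r in refs.items()}
    return design_probes(gh16, k=probe_len)


def run_pipeline(pcfg: PipelineConfig, outdir=None) -> dict:
    """Run all six stages on a synthetic cohort and return the manifest."""
    pcfg.validate()
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": pcfg.seed,
        "thresholds": {
            "identity_min": pcfg.identity_min,
            "coverage_min": pcfg.coverage_min,
            "probe_len": pcfg.probe_len,
            "min_reads": pcfg.min_reads,
            "dom_threshold": pcfg.dom_threshold,
            "tie_margin": pcfg.tie_margin,
            "truncation_frac": pcfg.truncation_frac,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged per stage
                raise StageError(name, str(exc)) from exc
            manifest["stages"][name] = result
            return result
        return deco

    scfg = pcfg.simulation
    scfg.seed = pcfg.seed
    base = build_reference(pcfg.seed)

    st: dict = {}

    @stage("simulate")
    def _sim():
        st["refs"] = make_group_references(base, scfg)
        st["cohort"] = simulate_cohort(scfg, st["refs"])
        n_carriers = sum(s.truth.carries_pul for s in st["cohort"].samples)
        return {"n_samples": scfg.n_samples, "n_carriers": n_carriers}

    @stage("screen_assembly")
    def _screen():
        st["calls"] = screen_cohort(st["cohort"], base, pcfg)
        return {"n_complete": sum(c.complete for c in st["calls"].values())}

    @stage("classify")
    def _classify():
        profiles = {g: GroupProfile.from_reference(g, st["refs"][g])
                    for g in ("GI", "GII", "GIII")}
        st["haps"] = classify_cohort(st["calls"], profiles, pcfg)
        by_group: dict[str, int] = defaultdict(int)
        for h in st["haps"].values():
            if h is not None:
                by_group["+".join(sorted(h.groups))] += 1
        return {"calls_by_group": dict(by_group)}

    @stage("design_probes")
    def _probes():
        st["probes"] = design_cohort_probes(st["refs"], pcfg.probe_len)
        return {"probes": {p.probe_id: p.seq for p in st["probes"]},
                "gh16_offset": st["probes"][0].gh16_offset}

    @stage("screen_reads")
    def _reads():
        st["screens"] = read_screen_cohort(st["cohort"], st["probes"], pcfg)
        return {"n_positive": sum(r.positive for r in st["screens"].values()),
                "n_characterized": sum(r.call in ("single", "dominant", "multi")
                                       for r in st["screens"].values())}

    @stage("stats")
    def _stats():
        from pulhaplo.stats import prevalence
        n = len(st["cohort"].samples)
        pos = sum(r.positive for r in st["screens"].values())
        prev, ci = prevalence(pos, n)
        truth_groups = {s.sample_id: s.truth for s in st["cohort"].samples}
        agree = tot = 0
        for sid, r in st["screens"].items():
            g = dominant_group(r)
            if g is None:
                continue
            tot += 1
            agree += g in truth_groups[sid].true_groups
        return {"read_prevalence": prev, "ci": list(ci),
                "dominant_agreement": (agree / tot if tot else None)}

    manifest["hash"] = hashlib.sha256(
        json.dumps(manifest["stages"], sort_keys=True).encode()).hexdigest()
    if outdir is not None:
        from pulhaplo.io import ensure_dir, write_probe_fasta
        out = ensure_dir(outdir)
        st["cohort"].write(out)
        write_probe_fasta(out / "probes.fasta", st["probes"])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
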