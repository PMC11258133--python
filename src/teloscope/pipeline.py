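"""End-to-end pipeline driver.

Runs subsample -> trim -> telomere profiling -> k-mer profiling -> assembly
QC -> Circos export over the inputs named in a single structured (YAML or
dict) config, and writes one machine-readable JSON report.  Every stage is a
pure function of its inputs plus the configured seeds, so a rerun with the
same config produces a byte-identical report; timings and record counts are
logged to stderr only.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import circos, kmer, qc, read_prep, telomere
from .io import iter_reads, read_fasta

__all__ = ["PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("teloscope")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write ``report.json``.

    ``config`` is a mapping (or a path to a YAML file) with ``inputs``
    (paths: short_reads, and optionally kmer_reads, assembly, repeats_out,
    genes_gff, snp_vcf, sv_vcf, depth_tsv), optional per-stage ``params``
    and an ``out_dir``.  All named input paths are validated before any
    stage runs; any stage failure aborts with the stage name and cause.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = dict(config)
    inputs = dict(cfg.get("inputs") or {})
    params = {k: dict(v) for k, v in (cfg.get("params") or {}).items()}
    out_dir = Path(out_dir or cfg.get("out_dir") or "teloscope_out")

    if "short_reads" not in inputs:
        raise PipelineError("validate", "config must name inputs.short_reads")
    missing = [f"{k}={v}" for k, v in inputs.items() if not Path(v).exists()]
    if missing:
        raise PipelineError("validate", f"missing input path(s): {', '.join(missing)}")
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"sample": cfg.get("sample_id", "sample"), "stages": []}

    @_stage("subsample")
    def do_subsample():
        p = params.get("subsample", {})
        reads = list(iter_reads(inputs["short_reads"]))
        n = int(p.get("n", min(len(reads), read_prep.DEFAULT_SUBSAMPLE_N)))
        out = list(
            read_prep.subsample_reads(
                reads,
                n=n,
                seed=int(p.get("seed", 42)),
                allow_fewer=bool(p.get("allow_fewer", False)),
                first_n=bool(p.get("first_n", False)),
            )
        )
        log.info("subsample: %d of %d reads kept", len(out), len(reads))
        return out

    reads = do_subsample()
    report["stages"].append({"stage": "subsample", "n_reads": len(reads)})

    @_stage("trim")
    def do_trim():
        p = params.get("trim", {})
        policy = read_prep.TrimPolicy(
            leading_trim=int(p.get("leading_trim", 10)),
            window_width=int(p.get("window_width", 60)),
            trailing_trim=int(p.get("trailing_trim", 81)),
        )
        return read_prep.trim_reads(reads, policy)

    trimmed = do_trim()
    report["stages"].append(
        {"stage": "trim", "n_windows": len(trimmed.windows), "n_skipped": trimmed.n_skipped}
    )

    @_stage("telomere")
    def do_telomere():
        p = params.get("telomere", {})
        table = telomere.profile_sample(
            trimmed.windows,
            sample_id=report["sample"],
            unit_min=int(p.get("unit_min", 6)),
            unit_max=int(p.get("unit_max", 10)),
            max_mismatch=int(p.get("max_mismatch", 0)),
            min_copies=int(p.get("min_copies", 4)),
            max_circular_edit=int(p.get("max_circular_edit", 1)),
        )
        call = telomere.call_sample_telomere(
            table,
            min_windows=int(p.get("min_windows", 50)),
            min_fraction=float(p.get("min_fraction", 0.5)),
        )
        table.to_dataframe().to_csv(out_dir / "motif_table.tsv", sep="\t", index=False)
        return table, call

    table, call = do_telomere()
    report["telomere"] = call
    report["stages"].append({"stage": "telomere", "n_tandem_windows": table.n_tandem})

    @_stage("kmer_profile")
    def do_kmer():
        p = params.get("kmer", {})
        src = inputs.get("kmer_reads", inputs["short_reads"])
        k = int(p.get("k", 21 if "kmer_reads" in inputs else 27))
        hist = kmer.count_kmers(iter_reads(src), k=k)
        kmer.write_histogram(hist, out_dir / "kmer_histogram.txt")
        try:
            profile = kmer.fit_genome_profile(hist, smooth=bool(p.get("smooth", False)))
            return hist, profile.to_dict()
        except ValueError as exc:
            log.warning("k-mer profile not fitted: %s", exc)
            return hist, {"error": str(exc)}

    hist, profile = do_kmer()
    report["genome_profile"] = profile
    report["stages"].append({"stage": "kmer_profile", "total_kmers": hist.total_kmers})

    if "assembly" in inputs:
        p = params.get("qc", {})

        @_stage("assembly_qc")
        def do_qc():
            assembly = read_fasta(inputs["assembly"])
            stats = qc.assembly_stats(assembly)
            motif = p.get("telomere_motif") or (
                call["call"] if call["call"] != "undetermined" else "TTTAGGG"
            )
            end_calls = qc.scan_contig_ends(
                assembly,
                motif,
                end_window=int(p.get("end_window", 10_000)),
                min_copies=int(p.get("end_min_copies", 10)),
                max_gap=int(p.get("max_gap", 50)),
            )
            contig_lengths = {c: len(s) for c, s in assembly.items()}
            repeats, class_totals = (
                qc.parse_repeatmasker_out(inputs["repeats_out"])
                if "repeats_out" in inputs
                else ([], {})
            )
            genes, cds = (
                qc.read_gff3_features(inputs["genes_gff"]) if "genes_gff" in inputs else ([], [])
            )
            snps = qc.read_snp_positions(inputs["snp_vcf"]) if "snp_vcf" in inputs else []
            svs, sv_counts = [], {}
            if "sv_vcf" in inputs:
                svs, sv_counts, _ = qc.filter_and_spectrum_svs(
                    inputs["sv_vcf"], min_sv_size=int(p.get("min_sv_size", 50))
                )
            depth = qc.read_depth_tsv(inputs["depth_tsv"]) if "depth_tsv" in inputs else None
            bins = qc.compute_bins(
                contig_lengths,
                depth=depth,
                repeat_intervals=repeats,
                genes=genes,
                snps=snps,
                svs=svs,
                bin_width=int(p.get("bin_width", qc.DEFAULT_BIN_WIDTH)),
                min_contig_len=int(p.get("min_contig_len", 0)),
            )
            qc.bins_to_dataframe(bins).to_csv(out_dir / "bins.tsv", sep="\t", index=False)
            split = qc.repeat_split_depth_summary(bins) if len(bins) >= 2 else None
            n_affected, _per_gene = qc.genes_affected_by_sv(cds, svs)
            return stats, end_calls, class_totals, sv_counts, split, n_affected, bins

        stats, end_calls, class_totals, sv_counts, split, n_affected, bins = do_qc()
        report["assembly_stats"] = stats.__dict__
        report["contig_end_telomeres"] = [c.__dict__ for c in end_calls]
        report["repeat_class_totals_bp"] = class_totals
        report["sv_type_counts"] = sv_counts
        report["repeat_split_depth"] = split
        report["genes_affected_by_sv"] = n_affected
        report["stages"].append({"stage": "assembly_qc", "n_bins": len(bins)})

        @_stage("circos_export")
        def do_export():
            return circos.export_circos_tracks(bins, out_dir / "circos")

        if bins:
            trackset = do_export()
            report["circos"] = {
                "karyotype": str(trackset.karyotype),
                "tracks": {k: str(v) for k, v in trackset.tracks.items()},
                "ranges": {k: list(v) for k, v in trackset.ranges.items()},
            }
            report["stages"].append({"stage": "circos_export", "n_tracks": len(trackset.tracks)})

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
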