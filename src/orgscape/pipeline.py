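"""One-command pipeline: all analysis stages over one genome, written as a
deterministic report bundle (TSVs, BED, JSON summary).

Defaults follow the standard analysis settings for this kind of survey:
palindrome arms 8-100 bp, spacers 0-10 bp, at most one arm mismatch;
dotplot word size 15; G4Hunter window 25 and threshold 1.2. Every tunable
is echoed into the JSON summary so a bundle is self-describing.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .composition import composition_report, dotplot_matches
from .frames import codon_usage, phase_bias_report, rarity_categories, six_frame_profile
from .genome_io import partition_genome, read_annotation, read_genome, spliced_cds
from .motifs import census, detect_arrays, load_motif_config
from .palindromes import ScanConfig, rank_ips, scan_palindromes
from .quadruplex import find_pqs

log = logging.getLogger("orgscape")


@dataclass
class RunConfig:
    genome: str
    annotation: str | None = None
    motifs: str | None = None  # JSON motif set; None = packaged default
    out_dir: str = "orgscape_out"
    topology_override: str | None = None
    arm_min: int = 8
    arm_max: int = 100
    spacer_min: int = 0
    spacer_max: int = 10
    max_mismatch: int = 1
    dotplot_word: int = 15
    pqs_window: int = 25
    pqs_threshold: float = 1.2
    pqs_count_mode: str = "regions"
    array_min_copies: int = 3
    array_max_gap: int = 20
    dotplot_max_len: int = 50_000  # self-dotplot coordinates emitted only below this size
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)


def default_motif_set_path() -> Path:
    return Path(importlib.resources.files("orgscape") / "motif_sets" / "leontynka_plastome.json")


def run(config: RunConfig) -> dict:
    """Execute every stage; returns the JSON-ready summary dict.

    Raises RuntimeError naming the failing stage; partial outputs are kept
    and MANIFEST.txt records which stages completed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {"config": asdict(config)}
    manifest_path = out / "MANIFEST.txt"

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                manifest_path.write_text("\n".join(completed + [f"FAILED: {name}: {exc}"]) + "\n")
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            completed.append(name)
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        rec = read_genome(config.genome, topology_override=config.topology_override)
        if config.annotation:
            rec.features.extend(read_annotation(config.annotation, genome_length=len(rec)))
        state["rec"] = rec
        state["partition"] = partition_genome(rec)

    @stage("composition")
    def _composition():
        rep = composition_report(state["rec"], state["partition"])
        pd.DataFrame([rep.as_row()]).to_csv(out / "composition.tsv", sep="\t", index=False)
        summary["composition"] = rep.as_row()

    @stage("palindromes")
    def _palindromes():
        cfg = ScanConfig(config.arm_min, config.arm_max, config.spacer_min, config.spacer_max,
                         config.max_mismatch)
        hits = scan_palindromes(state["rec"], cfg)
        state["ip_hits"] = hits
        table = rank_ips(hits, "spacer_masked", state["partition"])
        table.to_csv(out / "ip_ranking.tsv", sep="\t", index=False)
        with open(out / "ip_hits.bed", "w") as fh:
            for h in hits:
                fh.write(f"{state['rec'].id}\t{h.start}\t{h.end}\t{h.form()}\t{h.mismatches}\t+\n")
        summary["palindromes"] = {"n_hits": len(hits), "n_forms": int(len(table))}

    @stage("census")
    def _census():
        motif_path = config.motifs or default_motif_set_path()
        motifs = load_motif_config(motif_path)
        state["motifs"] = motifs
        counts = census(motifs, state["rec"], state["partition"])
        counts.by_partition.to_csv(out / "census.tsv", sep="\t", index=False)
        counts.per_gene_exon.to_csv(out / "census_per_gene.tsv", sep="\t", index=False)
        state["census"] = counts
        arrays = []
        for name, hits in counts.hits.items():
            for arr in detect_arrays(hits, config.array_min_copies, config.array_max_gap):
                arrays.append({"motif": name, "start": arr.start, "end": arr.end,
                               "n_hits": arr.n_hits, "period": arr.period,
                               "interleaved": arr.interleaved})
        pd.DataFrame(arrays, columns=["motif", "start", "end", "n_hits", "period", "interleaved"]).to_csv(
            out / "arrays.tsv", sep="\t", index=False
        )
        summary["census"] = {
            row["motif"]: int(row["total"]) for _, row in counts.by_partition.iterrows()
        }
        summary["arrays"] = {"n_arrays": len(arrays)}

    @stage("frames")
    def _frames():
        rec = state["rec"]
        genes = sorted({f.gene_name for f in rec.features if f.kind == "CDS"})
        if not genes:
            summary["frames"] = {"note": "no CDS features; frame analysis skipped"}
            return
        cds_set = [spliced_cds(rec, g) for g in genes]
        usage = codon_usage(cds_set)
        rarity = rarity_categories(usage)
        state["rarity"] = rarity
        with open(out / "rarity.json", "w") as fh:
            json.dump({"category": rarity.category,
                       "rare_amino_acids": sorted(rarity.rare_amino_acids),
                       "total_codons": usage.total_codons}, fh, indent=1)
        frames_rows = []
        for mp in state.get("motifs", []):
            if len(mp) < 3:
                continue
            prof = six_frame_profile(mp, rarity)
            t = prof.table.reset_index()
            t.insert(0, "motif", mp.name)
            frames_rows.append(t)
        if frames_rows:
            pd.concat(frames_rows).to_csv(out / "frame_profiles.tsv", sep="\t", index=False)
        exonic = [h for name in state["census"].hits for h in state["census"].hits[name] if h.partition == "exon"]
        bias = phase_bias_report(exonic, rarity)
        bias.contingency.to_csv(out / "phase_bias.tsv", sep="\t")
        summary["frames"] = {
            "total_codons": usage.total_codons,
            "n_exonic_hits": len(exonic),
            "in_frame_stops": bias.in_frame_stop_total,
            "rare_amino_acids": sorted(rarity.rare_amino_acids),
        }

    @stage("pqs")
    def _pqs():
        rec = state["rec"]
        regions, density = find_pqs(rec, config.pqs_window, config.pqs_threshold, config.pqs_count_mode)
        _, density_windows = find_pqs(rec, config.pqs_window, config.pqs_threshold, "windows")
        with open(out / "pqs.bed", "w") as fh:
            for r in regions:
                strand = "+" if r.strand > 0 else "-"
                fh.write(f"{rec.id}\t{r.start}\t{r.end}\tPQS\t{r.score:.3f}\t{strand}\n")
        dens = pd.DataFrame([
            {"genome": rec.id, "length_bp": len(rec), "mode": "regions",
             "n": len(regions), "per_1000bp": round(len(regions) / len(rec) * 1000, 3)},
            {"genome": rec.id, "length_bp": len(rec), "mode": "windows",
             "n": int(density_windows * len(rec) / 1000 + 0.5), "per_1000bp": round(density_windows, 3)},
        ])
        dens.to_csv(out / "pqs_density.tsv", sep="\t", index=False)
        summary["pqs"] = {"n_regions": len(regions),
                          "density_regions_per_1000bp": round(len(regions) / len(rec) * 1000, 3),
                          "density_windows_per_1000bp": round(density_windows, 3)}

    @stage("dotplot")
    def _dotplot():
        rec = state["rec"]
        if len(rec) > config.dotplot_max_len:
            summary["dotplot"] = {"note": f"genome over {config.dotplot_max_len} bp; coordinates not emitted"}
            return
        dm = dotplot_matches(rec.seq, word=config.dotplot_word)
        pd.DataFrame(dm.matches, columns=["x", "y", "orientation"]).to_csv(
            out / "dotplot_self.tsv", sep="\t", index=False
        )
        summary["dotplot"] = {"word": dm.word, "n_matches": len(dm.matches)}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    manifest_path.write_text("\n".join(completed) + "\n")
    return summary


__all__ = ["RunConfig", "run", "default_motif_set_path"]
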