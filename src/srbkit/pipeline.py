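"""Orchestration: census -> ectodomain -> alignment/motif -> structure stages.

One declarative config drives both stages; every threshold that matters
(expansion flag length, conservation mask, RMSD bin edges, probe radius, pTM
gate, minimum expansion run) lives in the config, not in code.  Outputs are
plain TSV/FASTA/JSON under a run directory with a machine-readable manifest,
and are byte-deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import census as census_mod
from . import cavity as cavity_mod
from . import ectodomain as ecto_mod
from . import motifscan as motif_mod
from . import msa as msa_mod
from . import structcomp as struct_mod

log = logging.getLogger("srbkit")


@dataclass
class Thresholds:
    flag_threshold: int = 500
    conservation: float = 0.40
    bin_edges: tuple[float, float] = (1.5, 2.7)
    probe_small: float = 0.9
    probe_bulk: float = 3.0
    grid_spacing: float = 1.0
    ptm_gate: float = 0.7
    min_run: int = 10
    max_overlap: int = 10
    max_n_tail: int = 400
    d_pair: float = 5.0

    def __post_init__(self):
        for name in ("flag_threshold", "conservation", "probe_small", "probe_bulk",
                     "grid_spacing", "ptm_gate", "min_run", "d_pair"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # census inputs
    fasta: str | None = None
    hits: str | None = None
    hits_dialect: str = "domtblout"
    tm_table: str | None = None
    tm_dialect: str = "tmhmm"
    use_hydropathy: bool = False
    clade_map: str | None = None
    # compare inputs
    alignment: str | None = None
    ref_id: str | None = None
    bridge_pairs: tuple[tuple[int, int], ...] = ()
    motifs: str | None = None
    structures: str | None = None
    reference_structure: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("thresholds", {}) or {}).items()
        })
        if "bridge_pairs" in raw and raw["bridge_pairs"]:
            raw["bridge_pairs"] = tuple(tuple(p) for p in raw["bridge_pairs"])
        return cls(thresholds=thr, **raw)


def _require(paths: Mapping[str, str | None]) -> None:
    missing = [f"{k}: {v}" for k, v in paths.items() if v is not None and not Path(v).exists()]
    if missing:
        raise FileNotFoundError("missing inputs: " + "; ".join(missing))


def _read_clade_map(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        taxon, clade = line.split("\t")[:2]
        out[taxon] = clade
    return out


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Census stage
# ---------------------------------------------------------------------------

def run_census(config: RunConfig) -> dict:
    """FASTA + hit/TM tables -> architecture calls, census, ectodomain exports."""
    if config.fasta is None or config.hits is None:
        raise ValueError("census needs fasta and hits inputs")
    if config.tm_table is None and not config.use_hydropathy:
        raise ValueError("census needs a tm_table or use_hydropathy: true")
    _require({
        "fasta": config.fasta, "hits": config.hits,
        "tm_table": config.tm_table, "clade_map": config.clade_map,
    })
    thr = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = census_mod.read_fasta(config.fasta)
    n_input = len(records)
    records = census_mod.dedupe_identical(records)
    n_dedup = len(records)
    hits = census_mod.read_domain_hits(config.hits, config.hits_dialect)
    hits_by_seq: dict[str, list] = {}
    for h in hits:
        hits_by_seq.setdefault(h.seq_id, []).append(h)
    tms: list[census_mod.TMSegment] = []
    if config.tm_table is not None:
        tms.extend(census_mod.read_tm_table(config.tm_table, config.tm_dialect))
    if config.use_hydropathy:
        for rec in records:
            tms.extend(census_mod.predict_tm_hydropathy(rec))
    tms_by_seq: dict[str, list] = {}
    for t in tms:
        tms_by_seq.setdefault(t.seq_id, []).append(t)

    calls = [
        census_mod.classify_architecture(
            rec, hits_by_seq.get(rec.id, []), tms_by_seq.get(rec.id, []),
            max_overlap=thr.max_overlap, max_n_tail=thr.max_n_tail,
        )
        for rec in records
    ]
    arch = pd.DataFrame(
        {
            "seq_id": [c.seq_id for c in calls],
            "label": [c.label for c in calls],
            "ecto_start": [c.ecto_span[0] if c.ecto_span else "" for c in calls],
            "ecto_end": [c.ecto_span[1] if c.ecto_span else "" for c in calls],
            "n_cd36_domains": [c.n_cd36_domains for c in calls],
            "n_tm": [len(tms_by_seq.get(c.seq_id, [])) for c in calls],
        }
    ).sort_values("seq_id", kind="stable")
    _write_tsv(arch, out / "architecture.tsv")

    taxon_of = {rec.id: rec.taxon for rec in records}
    if config.clade_map:
        clade_of = _read_clade_map(config.clade_map)
    else:
        clade_of = {t: "unassigned" for t in set(taxon_of.values())}
    summary = census_mod.census_summary(calls, taxon_of, clade_of)
    _write_tsv(summary, out / "census.tsv")

    by_id = {rec.id: rec for rec in records}
    ectos = [
        ecto_mod.extract_ectodomain(by_id[c.seq_id], c, flag_threshold=thr.flag_threshold)
        for c in calls
        if c.label == "SR-B"
    ]
    ectos.sort(key=lambda e: e.seq_id)
    census_mod.write_fasta(
        [census_mod.SequenceRecord(e.seq_id, taxon_of[e.seq_id], e.sequence) for e in ectos],
        out / "ectodomains.fasta",
    )
    clade_of_seq = {e.seq_id: clade_of[taxon_of[e.seq_id]] for e in ectos}
    if ectos:
        per_clade, per_seq = ecto_mod.length_stats(
            ectos, clade_of_seq, flag_threshold=thr.flag_threshold
        )
        _write_tsv(per_seq.sort_values("seq_id", kind="stable"), out / "lengths.tsv")
        _write_tsv(per_clade, out / "lengths_by_clade.tsv")
    n_cd36 = sum(1 for c in calls if c.label != "non_cd36")
    n_srb = sum(1 for c in calls if c.label == "SR-B")
    log.info("census: %d input, %d after dedupe, %d CD36 hits, %d SR-B",
             n_input, n_dedup, n_cd36, n_srb)
    manifest = {
        "stage": "census",
        "seed": config.seed,
        "counts": {
            "input_sequences": n_input,
            "after_dedupe": n_dedup,
            "cd36_hit_sequences": n_cd36,
            "srb": n_srb,
            "label_counts": {lab: int(sum(c.label == lab for c in calls))
                             for lab in census_mod.ARCH_LABELS},
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Compare stage
# ---------------------------------------------------------------------------

def run_compare(config: RunConfig) -> dict:
    """Alignment + motif + structure comparison against a designated reference."""
    _require({
        "alignment": config.alignment, "motifs": config.motifs,
        "reference_structure": config.reference_structure,
    })
    thr = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stage": "compare", "seed": config.seed}

    if config.alignment:
        aln = msa_mod.read_alignment(config.alignment)
        cons = msa_mod.conservation(aln)
        _write_tsv(
            pd.DataFrame({
                "column": np.arange(1, aln.n_cols + 1),
                "conservation": cons,
                "conserved": cons >= thr.conservation,
            }),
            out / "conservation.tsv",
        )
        cons_seq = msa_mod.consensus(aln)
        (out / "consensus.fasta").write_text(f">consensus\n{cons_seq}\n")
        manifest["consensus_length"] = len(cons_seq)
        manifest["mean_pairwise_identity"] = round(msa_mod.mean_pairwise_identity(aln), 6)
        ref_id = config.ref_id or aln.ids[0]
        expansions = msa_mod.detect_expansion_columns(aln, ref_id, min_run=thr.min_run)
        rows = []
        for rid in sorted(expansions):
            exp = expansions[rid]
            for (a, b, n), (before, after) in zip(exp.runs, exp.anchors):
                rows.append({
                    "seq_id": rid, "start_col": a, "end_col": b, "n_residues": n,
                    "ref_before": before if before is not None else "",
                    "ref_after": after if after is not None else "",
                })
        _write_tsv(
            pd.DataFrame(rows, columns=[
                "seq_id", "start_col", "end_col", "n_residues", "ref_before", "ref_after",
            ]),
            out / "expansions_sequence.tsv",
        )
        if config.bridge_pairs:
            calls = msa_mod.map_bridge_cysteines(
                aln, ref_id, config.bridge_pairs, expansions=expansions
            )
            _write_tsv(msa_mod.bridge_calls_table(calls), out / "bridges.tsv")
        if config.motifs:
            pwms = motif_mod.read_meme_motifs(config.motifs)
            seqs = [(rid, aln.ungapped(rid)) for rid in aln.ids]
            scaled, passes, frac = motif_mod.motif_presence(seqs, pwms)
            scaled.round(4).rename_axis("seq_id").reset_index().pipe(
                _write_tsv, out / "heatmap.tsv"
            )
            passes.rename_axis("seq_id").reset_index().pipe(_write_tsv, out / "passes.tsv")
            manifest["motif_pass_fraction"] = {k: round(float(v), 6) for k, v in frac.items()}

    if config.structures and config.reference_structure:
        ref = struct_mod.read_structure(config.reference_structure)
        paths = sorted(Path(config.structures).glob("*.pdb"))
        structures = [struct_mod.read_structure(p) for p in paths]
        structures = [s for s in structures if s.id != ref.id]
        kept, skipped = struct_mod.filter_by_ptm(structures, min_ptm=thr.ptm_gate)
        manifest["ptm_skipped"] = sorted(skipped)
        exp_rows, cav_reports, pair_rows = [], [], []
        for q in kept:
            res = struct_mod.superpose_iterative(
                ref, q, d_pair=thr.d_pair, bin_edges=thr.bin_edges
            )
            res.to_json(out / f"superposition_{q.id}.json")
            for (ri, qi, d), b in zip(res.pairs, res.bins):
                pair_rows.append({
                    "query_id": q.id, "ref_residue": ri + 1, "query_residue": qi + 1,
                    "distance": round(d, 4), "bin": b,
                })
            for seg in struct_mod.detect_structural_expansions(
                res, min_run=thr.min_run, n_query=len(q)
            ):
                exp_rows.append({
                    "query_id": q.id, "start": seg.start, "end": seg.end,
                    "length": seg.length,
                    "ref_before": seg.ref_anchor_before or "",
                    "ref_after": seg.ref_anchor_after or "",
                    "terminal": seg.terminal,
                })
            cav_reports.append(cavity_mod.grid_voids(
                q, probe_small=thr.probe_small, probe_bulk=thr.probe_bulk,
                spacing=thr.grid_spacing,
            ))
        _write_tsv(
            pd.DataFrame(pair_rows, columns=[
                "query_id", "ref_residue", "query_residue", "distance", "bin",
            ]),
            out / "residue_pairs.tsv",
        )
        _write_tsv(
            pd.DataFrame(exp_rows, columns=[
                "query_id", "start", "end", "length", "ref_before", "ref_after", "terminal",
            ]),
            out / "expansions_structure.tsv",
        )
        _write_tsv(cavity_mod.summarize_voids(cav_reports), out / "cavities.tsv")
    manifest["outputs"] = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
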