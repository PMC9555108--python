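"""End-to-end orchestration: simulate -> qc -> consensus -> quantify ->
diff -> annotate -> separate.

Each stage writes its outputs under the run directory and registers them
(with SHA-256 checksums and record counts) in a machine-readable
manifest.  Nothing in the manifest depends on wall time, so re-running an
identical config reproduces it byte for byte.  Stage failures abort with
an error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .diff import PoissonDifferentialModel
from .intervals import IntervalSet, read_bed, read_sample_sheet, write_bed
from .profiles import (
    enrichment_scores,
    feature_distribution,
    metagene_profile,
    separability,
)
from .qc import qc_report
from .quant import (
    count_matrix,
    high_confidence_hmrs,
    merge_replicates,
    merged_hmr_universe,
    rpkm,
    tile_genome,
)
from .simulate import simulate_dataset, write_fixture_bundle

__all__ = ["run_pipeline", "StageError"]

log = logging.getLogger("cfhydroxy")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Recorder:
    def __init__(self, out: Path):
        self.out = out
        self.stages: list[dict] = []
        self.current: dict | None = None

    def start(self, name: str):
        self.current = {"stage": name, "outputs": [], "records": {}}
        log.info("start", extra={"stage": name})

    def add(self, path: Path, n_records: int | None = None):
        entry = {"path": str(path.relative_to(self.out)), "sha256": _sha256(path)}
        if n_records is not None:
            entry["n_records"] = n_records
        self.current["outputs"].append(entry)

    def note(self, **kv):
        self.current["records"].update(kv)

    def finish(self):
        self.current["status"] = "completed"
        self.stages.append(self.current)
        log.info("done", extra={"stage": self.current["stage"]})
        self.current = None


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all seven stages; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _Recorder(out)

    def stage(name):
        def deco(fn):
            rec.start(name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise StageError(name, exc) from exc
            rec.finish()
            return result

        return deco

    # -- 1. simulate (or load) ---------------------------------------------
    @stage("simulate")
    def _sim():
        if config.simulate is not None:
            ds = simulate_dataset(config.simulate)
            write_fixture_bundle(config.simulate, out / "sim", dataset=ds)
            for p in sorted((out / "sim").rglob("*")):
                if p.is_file():
                    rec.add(p)
            rec.note(n_samples=len(ds.samples), n_hmrs=len(ds.universe))
            return ds
        entries = read_sample_sheet(config.sample_sheet)
        base = Path(config.sample_sheet).parent
        genome = pd.read_csv(config.genome, sep="\t")
        genome_map = dict(zip(genome["chrom"], genome["length"].astype(int)))
        fragments = {
            e.sample_id: read_bed(base / e.fragments_path) for e in entries
        }
        peaks = {e.sample_id: read_bed(base / e.peaks_path) for e in entries}

        class _Loaded:
            pass

        ds = _Loaded()
        ds.samples, ds.fragments, ds.peaks = entries, fragments, peaks
        ds.conversions, ds.spikeins, ds.features, ds.genes = {}, None, None, None
        ds.config = None
        ds.genome_map = genome_map
        rec.note(n_samples=len(entries))
        return ds

    ds = _sim
    sim_cfg = config.simulate
    genome_map = sim_cfg.genome_map if sim_cfg is not None else ds.genome_map
    if config.exclude_groups:
        keep = [s for s in ds.samples if s.group not in config.exclude_groups]
        ds.samples = keep

    # -- 2. qc ---------------------------------------------------------------
    @stage("qc")
    def _qc():
        qdir = out / "qc"
        qdir.mkdir(exist_ok=True)
        kept_fragments = {}
        for e in ds.samples:
            sid = e.sample_id
            conv = ds.conversions.get(sid) if ds.conversions else None
            frags = ds.fragments[sid]
            if conv is not None and len(conv):
                report = qc_report(
                    conv,
                    fragments=frags,
                    spikeins=ds.spikeins,
                    input_modified_fraction=(
                        sim_cfg.spikein_input_modified_fraction if sim_cfg else None
                    ),
                )
                keep_ids = set(
                    conv.loc[conv["n_converted"] >= 1, "read_id"].tolist()
                )
                keep_mask = frags.df["name"].isin(keep_ids).to_numpy()
                kept_fragments[sid] = IntervalSet(
                    frags.df.loc[keep_mask], label=sid
                )
            else:
                report = qc_report(
                    pd.DataFrame(
                        {"read_id": [], "n_cytosines": [], "n_converted": [],
                         "is_spikein": [], "spikein_true_sites": []}
                    ),
                    fragments=frags,
                ) if len(frags) else None
                kept_fragments[sid] = frags
            if report is not None:
                rp = qdir / f"{sid}.qc.json"
                report.to_json(rp)
                rec.add(rp)
        rec.note(n_samples=len(ds.samples))
        return kept_fragments

    fragments = _qc

    # -- 3. consensus --------------------------------------------------------
    @stage("consensus")
    def _consensus():
        if config.universe == "tiles_1kb":
            uni = tile_genome(genome_map, bin_size=config.bin_size)
        else:
            by_group: dict[str, list] = {}
            for e in ds.samples:
                by_group.setdefault(e.group, []).append(ds.peaks[e.sample_id])
            group_hmrs = []
            for g, sets in sorted(by_group.items()):
                if len(sets) >= config.min_replicates:
                    group_hmrs.append(
                        high_confidence_hmrs(sets, min_replicates=config.min_replicates)
                    )
                else:
                    raise ValueError(
                        f"group {g!r} has {len(sets)} replicates; "
                        f"consensus needs >= {config.min_replicates}"
                    )
            uni = merged_hmr_universe(group_hmrs)
        p = out / "universe.bed"
        write_bed(uni.regions, p)
        rec.add(p, n_records=len(uni))
        rec.note(universe=uni.definition, n_regions=len(uni))
        return uni

    universe = _consensus

    # -- 4. quantify ---------------------------------------------------------
    @stage("quantify")
    def _quant():
        cm = count_matrix(universe, ds.samples, fragments=fragments)
        nm = rpkm(cm)
        gm = merge_replicates(cm)
        for name, frame in (
            ("counts.tsv", cm.to_frame()),
            ("rpkm.tsv", nm.to_frame()),
            ("group_counts.tsv", gm.to_frame()),
        ):
            p = out / name
            frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
            rec.add(p, n_records=len(frame))
        return cm, nm, gm

    cm, nm, gm = _quant

    # -- 5. diff -------------------------------------------------------------
    @stage("diff")
    def _diff():
        model = PoissonDifferentialModel(gm)
        fit_kwargs = dict(pseudocount=config.pseudocount)
        if config.preset is not None:
            fit_kwargs["preset"] = config.preset
        else:
            fit_kwargs.update(
                alpha=config.alpha, fc_min=config.fc_min, adjustment=config.adjustment
            )
        res = model.fit(**fit_kwargs)
        p = out / "psdhmr.tsv"
        res.to_tsv(p)
        rec.add(p, n_records=len(res.frame))
        for g in gm.groups:
            sig = res.significant_regions(g)
            bp = out / f"significant.{g}.bed"
            write_bed(sig, bp)
            rec.add(bp, n_records=len(sig))
        summary = res.group_summary()
        sp = out / "diff_summary.json"
        with open(sp, "w") as fh:
            json.dump(
                {
                    "params": {k: v for k, v in res.params.items() if k != "groups"}
                    | {"groups": res.params["groups"]},
                    "per_group": summary.to_dict(orient="records"),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        rec.add(sp)
        contrast_results = {}
        for cname, sides in sorted(config.contrasts.items()):
            cres = model.fit_contrast(
                sides["focal"], sides.get("other"), name=cname, **fit_kwargs
            )
            cp = out / f"contrast.{cname}.tsv"
            cres.to_tsv(cp)
            rec.add(cp, n_records=len(cres.frame))
            contrast_results[cname] = cres
        rec.note(n_significant=res.n_significant)
        return res

    res = _diff

    # -- 6. annotate ---------------------------------------------------------
    @stage("annotate")
    def _annotate():
        if ds.features is None:
            rec.note(skipped="no feature annotation available")
            return None
        dist = feature_distribution(universe.regions, ds.features)
        scores = enrichment_scores(universe.regions, ds.features, genome_map)
        p1 = out / "feature_distribution.tsv"
        dist.table.to_csv(p1, sep="\t", index=False, float_format="%.6g")
        rec.add(p1, n_records=len(dist.table))
        p2 = out / "enrichment_scores.tsv"
        scores.table.to_csv(p2, sep="\t", index=False, float_format="%.6g")
        rec.add(p2, n_records=len(scores.table))
        # per-group metagene profiles on the simulated gene models
        groups = sorted({e.group for e in ds.samples})
        prof_rows = []
        for g in groups:
            gsam = [e.sample_id for e in ds.samples if e.group == g]
            frames = [fragments[s].df for s in gsam]
            pooled = IntervalSet(pd.concat(frames, ignore_index=True), label=g)
            prof = metagene_profile(pooled, ds.genes, group=g)
            for i, v in enumerate(prof.values):
                prof_rows.append({"group": g, "bin": i, "value": v})
        p3 = out / "metagene.tsv"
        pd.DataFrame(prof_rows).to_csv(p3, sep="\t", index=False, float_format="%.6g")
        rec.add(p3, n_records=len(prof_rows))
        return dist, scores

    _annotate

    # -- 7. separate ---------------------------------------------------------
    @stage("separate")
    def _separate():
        sig_ids = set(res.significant()["region_id"])
        if len(sig_ids) < 2:
            rec.note(skipped="fewer than 2 significant regions")
            return None
        rids = pd.Index(universe.region_ids())
        mask = rids.isin(sig_ids)
        values = pd.DataFrame(
            nm.values[mask.nonzero()[0]], columns=nm.sample_ids
        )
        labels = [e.group for e in ds.samples]
        dist, sil = separability(values, labels)
        p = out / "separability.json"
        with open(p, "w") as fh:
            json.dump(
                {
                    "mean_silhouette": sil,
                    "n_regions": int(mask.sum()),
                    "groups": sorted(set(labels)),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        rec.add(p)
        dp = out / "distances.tsv"
        dist.to_csv(dp, sep="\t", float_format="%.6g")
        rec.add(dp)
        rec.note(mean_silhouette=sil)
        return sil

    _separate

    manifest = {
        "version": __version__,
        "parameters": config.to_dict(),
        "stages": rec.stages,
        "n_stages": len(rec.stages),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
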