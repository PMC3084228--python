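"""End-to-end off-target screening workflow.

Stage 1 screens a query binding site against a site library with EVD
significance; stage 2 transfers the query ligand into each significant
target, filters on steric clashes and normalized docking score; stage 3
keeps the stringent shortlist (p < p_stringent); stage 4 runs ensemble
MM/GBSA and trajectory stability diagnostics on snapshot ensembles for the
shortlist; stage 5 propagates the inhibition of surviving off-targets
through the signed interaction network. Every stage writes a TSV and a
manifest entry with a SHA-256 hash chained to its inputs, so a rerun with
identical config and seeds reproduces every output bit for bit.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import netprop, posedock, sitealign, sitecore, structio
from .energetics import (
    build_system,
    ensemble_binding_free_energy,
    load_forcefield,
    stability_check,
    synthetic_parameter_block,
)
from .errors import PipelineError

log = logging.getLogger("offpipe")


@dataclass
class PipelineConfig:
    """Thresholds, snapshot policy and seeds for a screening run."""

    p_significant: float = 1e-3
    p_stringent: float = 1e-4
    nds_max: float = 0.0
    site_cutoff: float = 5.0  # A
    rmsd_pass: float = 3.0  # A
    exit_threshold: float = 4.0  # A
    d_clash: float = 1.5  # A
    snapshot_interval_ps: float = 10.0
    n_snapshots: int = 10
    snapshot_sigma: float = 0.15  # A coordinate noise emulating MD jitter
    include_entropy: bool = True
    entropy_stride: int = 5
    n_background: int = 100  # decoy alignments for the EVD null
    n_score_decoys: int = 30  # decoy placements for the NDS background
    seed: int = 0
    # synthetic-demo geometry
    n_decoys: int = 30
    n_residues: int = 18
    n_ligand_atoms: int = 8
    pocket_depth: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_stringent <= self.p_significant < 1.0):
            raise PipelineError("need 0 < p_stringent <= p_significant < 1")
        for name in ("nds_max",):
            pass
        for name in ("site_cutoff", "rmsd_pass", "exit_threshold", "d_clash"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


class Manifest:
    """Hash-chained record of stage outputs."""

    def __init__(self, config: PipelineConfig):
        self.entries: list[dict] = []
        self.chain = _sha(json.dumps(asdict(config), sort_keys=True))
        self.config = asdict(config)

    def record(self, stage: str, filename: str, content: str) -> None:
        self.chain = _sha(self.chain + _sha(content))
        self.entries.append(
            {"stage": stage, "file": filename, "sha256": _sha(content), "chain": self.chain}
        )

    def dump(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.entries, "chain": self.chain},
            indent=2,
            sort_keys=True,
        )


def _mutate_one_residue(site: sitecore.BindingSite, seed: int) -> sitecore.BindingSite:
    """Rigid copy of a site with a single residue identity swapped."""
    rng = np.random.default_rng(seed)
    names = list(site.residue_names)
    k = int(rng.integers(0, len(names)))
    alternatives = [a for a in sitealign._3TO1 if a != names[k]]
    names[k] = alternatives[int(rng.integers(0, len(alternatives)))]
    return sitecore.BindingSite(
        parent_id=site.parent_id + ":planted",
        residue_ids=list(site.residue_ids),
        residue_names=names,
        ca_coords=site.ca_coords.copy(),
        gp=site.gp.copy(),
    )


def build_demo_inputs(config: PipelineConfig):
    """Synthetic screening problem: a query complex, one planted
    similar-site target (rigid site copy with one mutation, hosted on the
    query's own receptor) and ``n_decoys`` unrelated synthetic complexes."""
    query = structio.make_synthetic_complex(
        config.seed, config.n_residues, config.n_ligand_atoms, config.pocket_depth
    )
    query_site = sitecore.define_site_by_ligand(query, cutoff=config.site_cutoff)
    library: dict[str, sitecore.BindingSite] = {}
    complexes: dict[str, structio.ComplexModel] = {}
    planted = _mutate_one_residue(query_site, seed=config.seed + 1)
    library["planted"] = planted
    complexes["planted"] = query
    for k in range(config.n_decoys):
        c = structio.make_synthetic_complex(
            config.seed + 1000 + k,
            config.n_residues,
            config.n_ligand_atoms,
            config.pocket_depth,
        )
        tid = f"decoy{k:03d}"
        library[tid] = sitecore.define_site_by_ligand(c, cutoff=config.site_cutoff)
        complexes[tid] = c
    return query, query_site, library, complexes


def run_offtarget_screen(
    config: PipelineConfig,
    outdir,
    query: structio.ComplexModel | None = None,
    query_site: sitecore.BindingSite | None = None,
    library: dict | None = None,
    complexes: dict | None = None,
    network: netprop.SignedNetwork | None = None,
) -> dict:
    """Run all five stages; returns a result dict and writes TSVs plus a
    manifest under ``outdir``. Without explicit inputs the synthetic demo
    problem is generated from the config seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    if query is None:
        query, query_site, library, complexes = build_demo_inputs(config)

    def write(stage: str, name: str, content: str):
        path = outdir / name
        path.write_text(content)
        manifest.record(stage, name, content)
        (outdir / "manifest.json").write_text(manifest.dump())

    results: dict = {}
    try:
        # stage 1: binding-site screening
        log.info("stage 1: site screening against %d sites", len(library))
        params = sitealign.AlignParams(seed=config.seed)
        hits, background = sitealign.screen_sites(
            query_site,
            library,
            alpha=config.p_significant,
            alpha_stringent=config.p_stringent,
            params=params,
            n_background=config.n_background,
            seed=config.seed,
        )
        hit_df = pd.DataFrame(
            [{"target_id": h.target_id, "score": round(h.score, 6),
              "p_value": h.p_value, "tier": h.tier} for h in hits]
        )
        write("screen", "stage1_hits.tsv", hit_df.to_csv(sep="\t", index=False))
        write("screen", "stage1_background.tsv",
              pd.DataFrame({"score": np.round(background, 6)}).to_csv(sep="\t", index=False))
        significant = [h for h in hits if h.tier != "none"]
        results["hits"] = hits
        results["significant"] = [h.target_id for h in significant]

        # stage 2: pose transfer + clash/NDS filter
        log.info("stage 2: pose transfer for %d significant hits", len(significant))
        panels: dict[str, posedock.ScorePanel] = {}
        poses: dict[str, posedock.Pose] = {}
        rows = []
        for h in significant:
            target_site = library[h.target_id]
            aln = sitealign.align_sites(query_site, target_site, params)
            if aln.rotation is None:
                continue
            # alignment maps target onto query; ligand goes the other way
            R_inv = aln.rotation.T
            t_inv = -aln.translation @ aln.rotation
            pose = posedock.transfer_pose(
                query.ligand, R_inv, t_inv, transform_id=f"align:{h.target_id}"
            )
            receptor = complexes[h.target_id].receptor
            ff = load_forcefield(synthetic_parameter_block(complexes[h.target_id]))
            pose, score = posedock.local_optimize_pose(receptor, pose, ff)
            clashes = posedock.clash_report(receptor, pose, d_clash=config.d_clash)
            bg = posedock.decoy_background_scores(
                receptor, pose, ff, n_decoys=config.n_score_decoys, seed=config.seed
            )
            nds = posedock.normalized_docking_score(score, bg)
            panels[h.target_id] = posedock.ScorePanel(
                raw_score=score, clash_count=clashes, nds=nds, severe_clash=clashes > 0
            )
            poses[h.target_id] = pose
        retained = posedock.nds_filter(panels, nds_max=config.nds_max)
        for tid, p in panels.items():
            rows.append(
                {"target_id": tid, "raw_score": round(p.raw_score, 4),
                 "clash_count": p.clash_count, "nds": round(p.nds, 4),
                 "retained": p.retained}
            )
        write("pose", "stage2_scores.tsv",
              pd.DataFrame(rows).to_csv(sep="\t", index=False))
        results["retained"] = retained

        # stage 3: stringent shortlist
        shortlist = [
            h.target_id for h in significant
            if h.tier == "stringent" and h.target_id in retained
        ]
        write("shortlist", "stage3_shortlist.tsv",
              pd.DataFrame({"target_id": shortlist}).to_csv(sep="\t", index=False))
        results["shortlist"] = shortlist

        # stage 4: ensemble MM/GBSA + stability
        log.info("stage 4: MM/GBSA on %d shortlisted targets", len(shortlist))
        gbsa_rows, stab_rows = [], []
        for tid in shortlist:
            cm = structio.ComplexModel(
                complexes[tid].receptor,
                complexes[tid].ligand.with_coords(poses[tid].coords)
                if tid in poses else complexes[tid].ligand,
                complex_id=tid,
            )
            ff = load_forcefield(synthetic_parameter_block(cm))
            sysm = build_system(cm, ff)
            traj = structio.perturb_ensemble(
                cm, config.n_snapshots, config.snapshot_sigma,
                seed=config.seed + 7, interval_ps=config.snapshot_interval_ps,
            )
            bfe = ensemble_binding_free_energy(
                sysm, traj, include_entropy=config.include_entropy,
                entropy_stride=config.entropy_stride,
            )
            gbsa_rows.append(
                {"target": tid, "ligand": "QRY", "dH": round(bfe.dH, 4),
                 "dTS": round(bfe.dTS, 4), "dG": round(bfe.dG, 4),
                 "se_dG": round(bfe.se_dG, 4), "n_snapshots": bfe.n_snapshots}
            )
            fitted = structio.superpose_to_first(traj, selection=("CA", "CB"))
            rep = stability_check(
                fitted, backbone_selection=("CA", "CB"),
                rmsd_pass=config.rmsd_pass,
                exit_threshold=config.exit_threshold,
                site_cutoff=config.site_cutoff,
            )
            stab_rows.append(
                {"target": tid, "receptor_flag": rep.receptor_flag,
                 "ligand_flag": rep.ligand_flag,
                 "max_backbone_rmsd": round(rep.max_backbone_rmsd, 4),
                 "mean_ligand_rmsd": round(rep.mean_ligand_rmsd, 4)}
            )
        write("gbsa", "stage4_mmgbsa.tsv",
              pd.DataFrame(gbsa_rows).to_csv(sep="\t", index=False))
        write("gbsa", "stage4_stability.tsv",
              pd.DataFrame(stab_rows).to_csv(sep="\t", index=False))
        results["gbsa"] = gbsa_rows
        results["stability"] = stab_rows
        survivors = [
            r["target"] for r in stab_rows
            if r["receptor_flag"] == "PASS" and r["ligand_flag"] == "OK"
        ]
        results["survivors"] = survivors

        # stage 5: network propagation
        log.info("stage 5: network propagation")
        if network is None:
            network = load_example_network()
        inhibited = network.nodes_of_kind("off_target") if survivors else []
        prop = netprop.propagate(network, inhibited)
        write("network", "stage5_network.tsv", netprop.result_to_tsv(network, prop))
        results["network"] = prop
    except PipelineError:
        raise
    except Exception as exc:  # persist completed stages, name the stage
        stage = manifest.entries[-1]["stage"] if manifest.entries else "setup"
        raise PipelineError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    results["manifest"] = json.loads(manifest.dump())
    return results


def load_example_network() -> netprop.SignedNetwork:
    """The packaged illustrative off-target/pathway network (topology
    transcribed from the published figure description; not ground truth)."""
    ref = importlib.resources.files("offpipe.data") / "offtarget_network.tsv"
    with importlib.resources.as_file(ref) as path:
        return netprop.load_network(path)
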