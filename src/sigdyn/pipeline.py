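"""Pipeline orchestration: configuration, stage execution, report emission.

A :class:`PipelineConfig` names the inputs (structure directory, metadata
CSV, reference structure), the filtering thresholds, the elastic-network
parameters and mode windows, and the seed.  :func:`run_pipeline` executes
structure parsing → mapping/superposition → similarity matrices → PCA →
per-member GNM / mode matching → signature profiles → labeled-state
comparison, writing every result as CSV plus a JSON run manifest that logs
parameters, member drops and outputs.  All randomness flows from the single
configured seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble_align import MappedEnsemble, build_mapped_ensemble, impute_missing, iterative_superpose
from .enm import build_anm
from .pca_landscape import ensemble_pca, mobility_profile, project_members
from .signature_dynamics import (
    REGIMES,
    ensemble_gnm,
    match_modes,
    reference_spectrum,
    signature_profile,
    spectral_distance_matrix,
)
from .similarity import cluster_order, rmsd_matrix, sequence_identity_matrix
from .state_compare import (
    mode_overlap_map,
    random_split_overlap,
    randomized_split_null,
    split_comparison,
)
from .structure_io import load_metadata, parse_ca_structure, records_to_fasta

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    structure_dir: str
    metadata_csv: str
    reference_id: str
    reference_chain: str
    output_dir: str
    occupancy_threshold: float = 0.9
    min_identity: float = 0.2
    coverage_floor: float = 0.8
    gnm_cutoff: float = 10.0
    anm_cutoff: float = 15.0
    gamma: float = 1.0
    zero_tol: float = 1e-8
    spectral_window: tuple[int, int] = (1, 20)
    match_k: int = 60
    mode_map_k: int = 20
    regimes: tuple[str, ...] = ("global", "lf", "ltif", "fastest")
    subset_labels: tuple[str, str] = ("active", "inactive")
    null_reps: int = 500
    seed: int = 0
    pca_components: int = 10
    plot: bool = False

    def validate(self) -> None:
        for name in ("occupancy_threshold", "min_identity", "coverage_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gnm_cutoff <= 0 or self.anm_cutoff <= 0 or self.gamma <= 0:
            raise ValueError("ENM cutoffs and gamma must be positive")
        i, j = self.spectral_window
        if not 1 <= i <= j:
            raise ValueError(f"invalid spectral window {self.spectral_window}")
        for r in self.regimes:
            if r not in REGIMES:
                raise ValueError(f"unknown regime {r!r}")
        if self.null_reps < 1 or self.match_k < 1 or self.mode_map_k < 1:
            raise ValueError("null_reps, match_k and mode_map_k must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["spectral_window"] = list(self.spectral_window)
        data["regimes"] = list(self.regimes)
        data["subset_labels"] = list(self.subset_labels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("spectral_window", "regimes", "subset_labels"):
            if key in data:
                data[key] = tuple(data[key])
        config = cls(**data)
        config.validate()
        return config


def _write_matrix(mat, path: Path) -> None:
    df = pd.DataFrame(mat.values, index=mat.member_ids, columns=mat.member_ids)
    df.to_csv(path, float_format=FLOAT_FMT, index_label="member_id")


def _write_profile(prof, position_ids, occupancy, path: Path) -> None:
    pd.DataFrame(
        {
            "position": position_ids,
            "mean_msf": prof.mean_msf,
            "variance_msf": prof.variance_msf,
            "min_msf": prof.min_msf,
            "max_msf": prof.max_msf,
            "low_occupancy": (np.asarray(occupancy) < 1.0).astype(int),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def save_ensemble(ensemble: MappedEnsemble, out_dir: Path) -> list[str]:
    """Serialize an ensemble as a coordinates + mask + metadata CSV bundle."""
    out_dir.mkdir(parents=True, exist_ok=True)
    m, n = ensemble.n_members, ensemble.n_positions
    coords = ensemble.coords.reshape(m, 3 * n)
    cols = [f"{rid}_{ax}" for rid in ensemble.position_ids for ax in "xyz"]
    written = []
    for name, df in {
        "ensemble_coords.csv": pd.DataFrame(coords, index=ensemble.member_ids, columns=cols),
        "ensemble_mask.csv": pd.DataFrame(
            ensemble.mask.astype(int), index=ensemble.member_ids, columns=ensemble.position_ids
        ),
        "ensemble_members.csv": pd.DataFrame(
            {
                "member_id": ensemble.member_ids,
                "state_label": ensemble.labels,
                "species": ensemble.species,
            }
        ).set_index("member_id"),
        "ensemble_occupancy.csv": pd.DataFrame(
            {"position": ensemble.position_ids, "occupancy": ensemble.occupancy}
        ).set_index("position"),
    }.items():
        df.to_csv(out_dir / name, float_format=FLOAT_FMT, index_label=df.index.name or "member_id")
        written.append(name)
    return written


def load_structures(config: PipelineConfig):
    """Parse the reference and all metadata-listed member structures."""
    meta = load_metadata(Path(config.metadata_csv).read_text())
    structure_dir = Path(config.structure_dir)
    ref_text = (structure_dir / f"{config.reference_id}.pdb").read_text()
    reference = parse_ca_structure(ref_text, config.reference_chain, config.reference_id)
    records = []
    for mid, row in meta.rows.iterrows():
        rec = parse_ca_structure(
            (structure_dir / f"{mid}.pdb").read_text(), row["chain_id"], str(mid)
        )
        rec.species = row["species"]
        rec.state_label = row["state_label"]
        records.append(rec)
    return reference, records


def run_pipeline(config: PipelineConfig, ensemble: MappedEnsemble | None = None,
                 reference=None) -> dict:
    """Execute all stages and write the report bundle; returns the manifest.

    A pre-built ensemble (e.g. synthetic) plus its reference record can be
    passed directly; otherwise structures are parsed from the configured
    paths.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "sigdyn_version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "drop_log": [],
        "outputs": [],
        "stages": {},
    }
    outputs: list[str] = manifest["outputs"]

    def _done(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s done: %s", stage, info)

    # --- structures & ensemble -------------------------------------------
    records = None
    if ensemble is None:
        reference, records = load_structures(config)
        (out / "sequences.fasta").write_text(records_to_fasta(records))
        outputs.append("sequences.fasta")
        ensemble = build_mapped_ensemble(
            records,
            reference,
            occupancy_threshold=config.occupancy_threshold,
            min_identity=config.min_identity,
            coverage_floor=config.coverage_floor,
            drop_log=manifest["drop_log"],
        )
        ensemble = iterative_superpose(ensemble)
        n_in = len(records)
    else:
        if reference is None:
            raise ValueError("a pre-built ensemble requires its reference record")
        n_in = ensemble.n_members
    ensemble = impute_missing(ensemble) if not ensemble.imputed else ensemble
    outputs.extend(save_ensemble(ensemble, out))
    _done("ensemble", members_in=n_in, members_out=ensemble.n_members,
          positions=ensemble.n_positions)

    # --- similarity matrices ---------------------------------------------
    rmsd = rmsd_matrix(ensemble)
    _write_matrix(rmsd, out / "rmsd_matrix.csv")
    outputs.append("rmsd_matrix.csv")
    order_source = rmsd  # synthetic ensembles share one sequence
    if records is not None:
        by_id = {r.member_id: r for r in records}
        kept = [by_id[mid] for mid in ensemble.member_ids]
        seq_mat = sequence_identity_matrix(kept, min_identity=config.min_identity)
        _write_matrix(seq_mat, out / "seq_identity_matrix.csv")
        outputs.append("seq_identity_matrix.csv")
        if not np.isnan(seq_mat.values).any():
            order_source = seq_mat

    # --- PCA --------------------------------------------------------------
    pca = ensemble_pca(ensemble, k=config.pca_components)
    pd.DataFrame(
        {
            "component": np.arange(1, pca.n_components + 1),
            "eigenvalue_A2": pca.eigenvalues,
            "variance_fraction": pca.variance_fraction,
        }
    ).to_csv(out / "pca_variance.csv", index=False, float_format=FLOAT_FMT)
    proj = project_members(pca, ensemble, list(range(min(3, pca.n_components))))
    proj.to_csv(out / "pca_projections.csv", index=False, float_format=FLOAT_FMT)
    mob = pd.DataFrame({"position": ensemble.position_ids})
    for c in range(min(3, pca.n_components)):
        mob[f"PC{c + 1}_mobility"] = mobility_profile(pca, c).values
    mob.to_csv(out / "pca_mobility.csv", index=False, float_format=FLOAT_FMT)
    outputs += ["pca_variance.csv", "pca_projections.csv", "pca_mobility.csv"]
    _done("pca", components=pca.n_components,
          pc1_fraction=float(pca.variance_fraction[0]))

    # --- per-member GNM + matching ---------------------------------------
    spectra = ensemble_gnm(ensemble, cutoff=config.gnm_cutoff, gamma=config.gamma)
    dropped = set(ensemble.member_ids) - {s.member_id for s in spectra}
    for mid in sorted(dropped):
        manifest["drop_log"].append({"member_id": mid, "reason": "gnm_disconnected",
                                     "detail": f"cutoff {config.gnm_cutoff}"})
    if reference is not None:
        ref_spec = reference_spectrum(reference, ensemble,
                                      cutoff=config.gnm_cutoff, gamma=config.gamma)
    else:
        ref_spec = spectra[0]
    matched = [match_modes(s, ref_spec, k_max=config.match_k) for s in spectra]
    labels = [ensemble.labels[ensemble.member_index(s.member_id)] for s in matched]
    _done("gnm", members=len(matched), reference=ref_spec.member_id)

    # --- dynamics similarity ---------------------------------------------
    i, j = config.spectral_window
    sdm = spectral_distance_matrix(matched, i, j)
    _write_matrix(sdm, out / "spectral_distance_matrix.csv")
    order = cluster_order(order_source)
    pd.DataFrame(
        {"rank": np.arange(len(order)), "member_id": [ensemble.member_ids[k] for k in order]}
    ).to_csv(out / "cluster_order.csv", index=False)
    outputs += ["spectral_distance_matrix.csv", "cluster_order.csv"]

    # --- signature profiles ----------------------------------------------
    for regime in config.regimes:
        prof = signature_profile(matched, regime)
        name = f"signature_{regime}.csv"
        _write_profile(prof, ensemble.position_ids, ensemble.occupancy, out / name)
        outputs.append(name)
    _done("signature", regimes=list(config.regimes))

    # --- state comparison --------------------------------------------------
    la, lb = config.subset_labels
    n_a, n_b = labels.count(la), labels.count(lb)
    if n_a >= 2 and n_b >= 2:
        comp = split_comparison(matched, labels, "global", subset_labels=(la, lb))
        null = randomized_split_null(
            matched, (n_a, n_b), "global", n_reps=config.null_reps, seed=config.seed
        )
        pd.DataFrame(
            {
                "position": ensemble.position_ids,
                "difference": comp.difference,
                "variance_ratio": comp.variance_ratio,
                "null_q50": null.q50,
                "null_q95": null.q95,
                "null_q99": null.q99,
            }
        ).to_csv(out / "state_difference.csv", index=False, float_format=FLOAT_FMT)
        sub_a = [s for s, lab in zip(matched, labels) if lab == la]
        sub_b = [s for s, lab in zip(matched, labels) if lab == lb]
        k = min(config.mode_map_k, config.match_k)
        omap = mode_overlap_map(sub_a, sub_b, k)
        pd.DataFrame(omap.mean_overlap).to_csv(
            out / "mode_overlap_mean.csv", float_format=FLOAT_FMT, index=False
        )
        pd.DataFrame(omap.sd_overlap).to_csv(
            out / "mode_overlap_sd.csv", float_format=FLOAT_FMT, index=False
        )
        rand_diag = random_split_overlap(
            matched, (n_a, n_b), k, n_splits=5, seed=config.seed
        )
        outputs += ["state_difference.csv", "mode_overlap_mean.csv", "mode_overlap_sd.csv"]
        _done("state_compare", n_active=n_a, n_inactive=n_b,
              true_diagonal_overlap=omap.diagonal_mean,
              random_diagonal_overlap=rand_diag)
    else:
        _done("state_compare", skipped=f"subset sizes {n_a}/{n_b} too small")

    # --- optional ANM on the reference ------------------------------------
    if reference is not None:
        index = {rid: i for i, rid in enumerate(reference.residue_ids)}
        rows = [index[rid] for rid in ensemble.position_ids]
        anm = build_anm(reference.ca_coords[rows], cutoff=config.anm_cutoff,
                        gamma=config.gamma)
        from .enm import anm_pc_correlation

        n_slow = min(20, anm.n_modes)
        corr = np.array(
            [
                [anm_pc_correlation(anm.eigenvectors[m], pca.components[c])
                 for c in range(min(3, pca.n_components))]
                for m in range(n_slow)
            ]
        )
        df = pd.DataFrame(corr, columns=[f"PC{c + 1}" for c in range(corr.shape[1])])
        df.insert(0, "anm_mode", np.arange(1, n_slow + 1))
        df.to_csv(out / "anm_pc_correlation.csv", index=False, float_format=FLOAT_FMT)
        outputs.append("anm_pc_correlation.csv")
        best = int(np.argmax(corr[:, 0]))
        _done("anm", modes=anm.n_modes, best_pc1_mode=best + 1,
              best_pc1_correlation=float(corr[best, 0]))

    if config.plot:
        outputs.extend(_plots(out, rmsd, sdm, proj, matched, ensemble, config))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _plots(out, rmsd, sdm, proj, matched, ensemble, config) -> list[str]:
    """Optional, non-load-bearing heatmap / scatter / profile figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    order = cluster_order(rmsd)
    for mat, name in ((rmsd, "rmsd_heatmap.png"), (sdm, "spectral_distance_heatmap.png")):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(mat.values[np.ix_(order, order)], cmap="viridis_r")
        fig.colorbar(im, ax=ax, label=mat.metric)
        ax.set_title(mat.metric)
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        written.append(name)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in sorted(set(proj["state_label"])):
        sub = proj[proj["state_label"] == lab]
        ax.scatter(sub["PC1"], sub.get("PC2", 0 * sub["PC1"]), label=lab, s=12)
    ax.set_xlabel("PC1 (Å)")
    ax.set_ylabel("PC2 (Å)")
    ax.legend()
    fig.savefig(out / "pc_landscape.png", dpi=120)
    plt.close(fig)
    written.append("pc_landscape.png")
    prof = signature_profile(matched, "global")
    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(ensemble.n_positions)
    ax.fill_between(x, prof.min_msf, prof.max_msf, alpha=0.25, label="min–max")
    ax.fill_between(x, prof.mean_msf - np.sqrt(prof.variance_msf),
                    prof.mean_msf + np.sqrt(prof.variance_msf), alpha=0.5, label="±sd")
    ax.plot(x, prof.mean_msf, lw=0.8, color="green", label="mean")
    ax.set_xlabel("position")
    ax.set_ylabel("normalized MSF")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "signature_global.png", dpi=120)
    plt.close(fig)
    written.append("signature_global.png")
    return written
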