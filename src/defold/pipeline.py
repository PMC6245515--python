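"""End-to-end orchestration: alignment -> contacts -> torsions -> folding ->
model selection, with per-stage caching and provenance.

Every stage writes its artifacts into the run directory together with a
fingerprint (hash of its inputs and the relevant config slice).  Re-running
with unchanged inputs is a no-op for that stage.  The resolved config
snapshot is written as ``config.yaml`` so a run is reproducible from the run
directory plus the original inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import cg_sampler, dca, ensemble, msa as msa_mod, pdbio, restraints
from . import torsion_net as tn
from .config import RunConfig

logger = logging.getLogger("defold")


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on input {fingerprint[:12]}: {cause}")
        self.stage = stage
        self.cause = cause


def _fingerprint(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (bytes, bytearray)):
            h.update(p)
        elif isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _stage_cached(run_dir: Path, stage: str, fp: str, outputs: list[Path]) -> bool:
    marker = run_dir / f"{stage}.fingerprint"
    if marker.exists() and marker.read_text().strip() == fp:
        if all(o.exists() for o in outputs):
            logger.info("stage %s: cache hit", stage)
            return True
    return False


def _mark(run_dir: Path, stage: str, fp: str) -> None:
    (run_dir / f"{stage}.fingerprint").write_text(fp + "\n")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return {"a3m": "a3m", "sto": "stockholm", "stk": "stockholm",
            "stockholm": "stockholm"}.get(suffix, "fasta")


def run_pipeline(
    sequence: str,
    msa_path: str | Path,
    feature_path: str | Path,
    config: RunConfig,
    run_dir: str | Path,
    model: "tn.TorsionNet | str | Path | None" = None,
    reference_pdb: str | Path | None = None,
) -> Path:
    """Execute the full pipeline; returns the run directory.

    ``model`` may be a trained :class:`~defold.torsion_net.TorsionNet`, a
    checkpoint path, or None (a freshly initialized network — useful only
    for smoke runs).  ``reference_pdb`` adds RMSD/TM columns to the report.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    msa_path = Path(msa_path)
    feature_path = Path(feature_path)
    L = len(sequence)

    # --- stage: msa -------------------------------------------------------
    stage = "msa"
    fp = _fingerprint(msa_path, {
        "col": config.column_max_gap_fraction,
        "seq": config.sequence_max_gap_fraction,
        "id": config.identity_threshold,
        "order": config.columns_first,
    })
    trimmed_path = run_dir / "trimmed.fasta"
    weights_path = run_dir / "weights.tsv"
    try:
        if not _stage_cached(run_dir, stage, fp, [trimmed_path, weights_path]):
            alignment = msa_mod.read_msa(msa_path, _guess_format(msa_path))
            first, second = (
                (msa_mod.filter_columns, msa_mod.filter_sequences)
                if config.columns_first
                else (msa_mod.filter_sequences, msa_mod.filter_columns)
            )
            alignment = first(alignment, config.column_max_gap_fraction
                              if config.columns_first
                              else config.sequence_max_gap_fraction)
            alignment = second(alignment, config.sequence_max_gap_fraction
                               if config.columns_first
                               else config.column_max_gap_fraction)
            weights = msa_mod.compute_weights(alignment, config.identity_threshold)
            msa_mod.write_msa_fasta(alignment, trimmed_path)
            np.savetxt(weights_path, weights.weights, header="weight",
                       comments="")
            _mark(run_dir, stage, fp)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, fp, exc) from exc

    # --- stage: dca -------------------------------------------------------
    stage = "dca"
    fp = _fingerprint(trimmed_path, {
        "pc": config.pseudocount, "lh": config.lambda_h, "le": config.lambda_e,
        "score": config.contact_score, "sep": config.min_separation,
        "factor": config.contact_factor,
    })
    contacts_path = run_dir / "contacts.rr"
    di_path = run_dir / "di.tsv"
    try:
        if not _stage_cached(run_dir, stage, fp, [contacts_path, di_path]):
            alignment = msa_mod.read_msa(trimmed_path, "fasta")
            weights = msa_mod.SeqWeights(
                np.loadtxt(weights_path, skiprows=1, ndmin=1),
                config.identity_threshold,
            )
            freqs = dca.site_frequencies(alignment, weights, config.pseudocount)
            reg = (config.lambda_h,
                   config.lambda_e if config.lambda_e is not None
                   else 0.01 * (alignment.n_cols - 1))
            model_potts = dca.fit_plm(alignment, weights, reg=reg)
            score = (dca.direct_information(model_potts, freqs)
                     if config.contact_score == "di"
                     else dca.apc_frobenius(model_potts))
            k = int(config.contact_factor * alignment.n_cols)
            contacts = dca.rank_contacts(score, L=alignment.n_cols,
                                         min_separation=config.min_separation,
                                         k=k)
            dca.write_contacts(contacts, contacts_path)
            dca.write_di_tsv(score, di_path)
            _mark(run_dir, stage, fp)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, fp, exc) from exc

    # --- stage: torsion_net (predict) ------------------------------------
    stage = "torsion_net"
    try:
        if not feature_path.exists():
            raise FileNotFoundError(f"feature table not found: {feature_path}")
        fp = _fingerprint(feature_path, {"context": config.context})
        pred_path = run_dir / "torsions.tsv"
        if not _stage_cached(run_dir, stage, fp, [pred_path]):
            features = tn.read_feature_table(feature_path)
            if features.L != L:
                raise ValueError(
                    f"feature table rows ({features.L}) != sequence length ({L})"
                )
            if model is None:
                net = tn.build_model(tn.ArchitectureConfig(
                    context=config.context, init_mode=config.init_mode,
                    seed=config.seed))
            elif isinstance(model, tn.TorsionNet):
                net = model
            else:
                net = tn.build_model(tn.ArchitectureConfig(
                    context=config.context, init_mode=config.init_mode,
                    seed=config.seed))
                net.load(model)
            pred = tn.predict(net, features)
            tn.write_prediction_tsv(pred, pred_path)
            _mark(run_dir, stage, fp)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, _fingerprint(str(feature_path)), exc) from exc

    # --- stage: restraints + folding --------------------------------------
    stage = "cg_sampler"
    fp = _fingerprint(contacts_path, run_dir / "torsions.tsv", {
        "delta": config.torsion_half_width, "k": config.k_tor,
        "depth": config.contact_depth, "width": config.contact_width,
        "rc": config.contact_cutoff, "n_traj": config.n_traj,
        "steps": config.steps, "cap": config.capture_every,
        "T": config.temperature, "sigma": config.proposal_sigma,
        "seed": config.seed, "pair": config.enable_pair,
        "env": config.enable_env, "env_mag": config.env_magnitude,
    })
    traj_path = run_dir / "trajectories.pdb"
    energy_path = run_dir / "energies.tsv"
    trajectories = None
    try:
        data = np.loadtxt(run_dir / "torsions.tsv", skiprows=1)
        phi_pred, psi_pred = data[:, 1], data[:, 2]
        contacts = dca.read_contacts(contacts_path)
        bundle = restraints.bundle(
            phi_pred, psi_pred, contacts,
            delta=config.torsion_half_width, k_tor=config.k_tor,
            contact_depth=config.contact_depth,
            contact_width=config.contact_width, r_c=config.contact_cutoff,
        )
        options = cg_sampler.ForceFieldOptions(
            enable_pair=config.enable_pair, enable_env=config.enable_env,
            env_magnitude=config.env_magnitude,
        )
        if not _stage_cached(run_dir, stage, fp, [traj_path, energy_path]):
            conf0 = cg_sampler.build_extended(sequence)
            seeds = [config.seed + t for t in range(config.n_traj)]
            trajectories = cg_sampler.run_ensemble(
                conf0, bundle, seeds, config.steps,
                capture_every=config.capture_every,
                temperature=config.temperature,
                proposal_sigma=config.proposal_sigma, options=options,
            )
            final_frames = [t.frames[-1] for t in trajectories]
            pdbio.write_pdb(final_frames, traj_path)
            with open(energy_path, "w") as fh:
                fh.write("trajectory\tframe\tenergy\n")
                for t_id, t in enumerate(trajectories):
                    for f_id, e in enumerate(t.energies):
                        fh.write(f"{t_id}\t{f_id}\t{e:.6f}\n")
            _mark(run_dir, stage, fp)
        elif trajectories is None:
            # Cache hit on folding but selection still needs the ensemble:
            # rerun deterministically (same seeds -> bit-identical result).
            conf0 = cg_sampler.build_extended(sequence)
            seeds = [config.seed + t for t in range(config.n_traj)]
            trajectories = cg_sampler.run_ensemble(
                conf0, bundle, seeds, config.steps,
                capture_every=config.capture_every,
                temperature=config.temperature,
                proposal_sigma=config.proposal_sigma, options=options,
            )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, fp, exc) from exc

    # --- stage: ensemble ---------------------------------------------------
    stage = "ensemble"
    try:
        pool = ensemble.pool_frames(trajectories, last_n=config.last_n)
        clusters = ensemble.cluster(pool, cutoff=config.cluster_cutoff)
        reference = (pdbio.read_ca_trace(reference_pdb)
                     if reference_pdb is not None else None)
        rep = ensemble.report(pool, clusters, reference)
        ensemble.write_report_tsv(rep, run_dir / "report.tsv")
        top = ensemble.top_clusters(clusters, config.top_k)
        pdbio.write_pdb([pool.conformations[i] for i in top],
                        run_dir / "centroids.pdb")
        labels_path = run_dir / "cluster_labels.tsv"
        with open(labels_path, "w") as fh:
            fh.write("pool_index\ttrajectory\tframe\tcluster\n")
            for idx, (t_id, f_id) in enumerate(pool.provenance):
                fh.write(f"{idx}\t{t_id}\t{f_id}\t{clusters.labels[idx]}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, "final", exc) from exc

    logger.info("pipeline complete: %s", run_dir)
    return run_dir
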