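"""Dataset container I/O, volumetric parcel extraction, group distance
matrices, MDS embedding, and pipeline orchestration.

The on-disk dataset container is an HDF5 file with arrays ``/patterns``
(trials x n_dim), ``/labels``, ``/novel_id``, ``/run``, ``/session``,
``/batch``, ``/trial`` and root attributes ``observer_id``, ``condition``,
``parcel_id``, ``schema_version`` (plus any generator metadata).  The layout
is deliberately simple so that any implementation can read it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import NOVEL
from .dlda import fit_dlda, project
from .synth import ResponseDataset

logger = logging.getLogger("parcelrsa")

_SCHEMA_VERSION = 1
_ARRAYS = ("labels", "novel_id", "run", "session", "batch", "trial")


class IntegrityError(ValueError):
    """Container is missing arrays or violates dataset invariants."""


def write_dataset(dataset: ResponseDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["observer_id"] = dataset.observer_id
        f.attrs["condition"] = dataset.condition
        f.attrs["parcel_id"] = dataset.parcel_id
        for k, v in dataset.meta.items():
            if isinstance(v, (int, float, str, np.integer, np.floating)):
                f.attrs[f"meta_{k}"] = v
        f.create_dataset("patterns", data=dataset.patterns)
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("novel_id", data=dataset.novel_exemplar_id)
        f.create_dataset("run", data=dataset.run)
        f.create_dataset("session", data=dataset.session)
        f.create_dataset("batch", data=dataset.batch)
        f.create_dataset("trial", data=dataset.trial)


def read_dataset(path) -> ResponseDataset:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise IntegrityError(f"unsupported container schema: {version!r}")
        missing = [a for a in ("patterns",) + _ARRAYS if a not in f]
        if missing:
            raise IntegrityError(f"container missing array(s): {missing}")
        ds = ResponseDataset(
            patterns=f["patterns"][()], labels=f["labels"][()],
            novel_exemplar_id=f["novel_id"][()], run=f["run"][()],
            session=f["session"][()], batch=f["batch"][()], trial=f["trial"][()],
            observer_id=str(f.attrs.get("observer_id", "")),
            condition=str(f.attrs.get("condition", "")),
            parcel_id=str(f.attrs.get("parcel_id", "")),
            meta={k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")})
    if np.any((ds.labels == NOVEL) != (ds.novel_exemplar_id > 0)):
        raise IntegrityError("novel_id inconsistent with NOVEL labels")
    if np.any(ds.batch < 0):
        raise IntegrityError("negative batch index")
    return ds


# ---------------------------------------------------------------------------
# volumetric extraction

def parcel_extract(volume_4d, atlas_labels, events: pd.DataFrame, parcel_id: int,
                   n_timepoints: int = 9, onset_offset_s: float = 2.0,
                   tr_s: float | None = None) -> ResponseDataset:
    """Extract parcel-level spatiotemporal patterns from a 4-D volume.

    For every trial in ``events`` (columns: onset_s, object_id, and
    optionally novel_exemplar_id/run/session/trial), the ``n_timepoints``
    consecutive volumes starting ``onset_offset_s`` after stimulus onset are
    extracted for the voxels carrying the parcel's atlas label, and flattened
    voxel-major (all time points of voxel 1, then voxel 2, ...) into one
    N_t * N_vox vector.  Onsets are mapped to volumes by nearest-sample
    rounding at the repetition time (read from the header unless given).
    """
    import nibabel as nib

    img = volume_4d if hasattr(volume_4d, "get_fdata") else nib.load(str(volume_4d))
    atlas = (atlas_labels if hasattr(atlas_labels, "get_fdata")
             else nib.load(str(atlas_labels)))
    data = np.asarray(img.get_fdata())
    lab = np.asarray(atlas.get_fdata()).astype(np.int64)
    if data.shape[:3] != lab.shape:
        raise ValueError("volume and atlas grids differ")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if abs(tr_s - 1.0) > 1e-9:
        logger.warning("repetition time %.3f s != 1 s; onsets mapped by "
                       "nearest sample", tr_s)
    vox = np.flatnonzero(lab.ravel() == int(parcel_id))   # ascending linear index
    if len(vox) == 0:
        raise ValueError(f"no voxels carry atlas label {parcel_id}")
    flat = data.reshape(-1, data.shape[3])                # voxels x time
    n_scan = data.shape[3]
    patterns = []
    bad = []
    for i, row in events.reset_index(drop=True).iterrows():
        start = int(round((row["onset_s"] + onset_offset_s) / tr_s))
        if start < 0 or start + n_timepoints > n_scan:
            bad.append(i)
            continue
        win = flat[vox, start:start + n_timepoints]       # n_vox x n_t
        patterns.append(win.ravel())                      # voxel-major
    if bad:
        raise ValueError(f"trial window(s) exceed scan length: trials {bad}")
    X = np.asarray(patterns, dtype=np.float32)
    n = len(events)
    labels = events["object_id"].to_numpy(np.int64)
    get = lambda col, default: (events[col].to_numpy(np.int64)
                                if col in events else default)
    return ResponseDataset(
        patterns=X, labels=labels,
        novel_exemplar_id=get("novel_exemplar_id", np.zeros(n, np.int64)),
        run=get("run", np.ones(n, np.int64)),
        session=get("session", np.ones(n, np.int64)),
        batch=get("batch", np.zeros(n, np.int64)),
        trial=get("trial", np.arange(1, n + 1)),
        parcel_id=str(parcel_id),
        meta={"n_voxels": len(vox), "n_timepoints": n_timepoints, "tr_s": tr_s})


# ---------------------------------------------------------------------------
# group distance matrices and MDS

def group_distance_matrix(datasets: list[ResponseDataset], n_per_class: int = 50,
                          session_windows: tuple[int, int] | None = None,
                          n_label_perms: int = 100, rng_seed=0,
                          novelty_variant: bool = False,
                          n_novel_per_window: int = 50,
                          n_recurring_classes_novelty: int = 3,
                          n_recurring_per_class_novelty: int = 20
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Group-average pairwise distance matrix over sampled exemplars.

    Per dataset: a fixed DLDA subspace is fitted on all recurring trials,
    ``n_per_class`` exemplars per recurring class are sampled from each
    session window (default: first and last session), and their pairwise
    distance matrix is computed.  Because activity patterns of different
    subjects are not directly comparable, the recurring class assignment is
    permuted ``n_label_perms`` times and the matrix averaged over
    permutations before averaging across datasets.  The novelty variant
    samples novel exemplars per window plus a few recurring classes.

    Returns (matrix, annotation frame with class/window per row).
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    if session_windows is None:
        sessions = np.unique(datasets[0].session)
        session_windows = (int(sessions[0]), int(sessions[-1]))
    acc = None
    annot = None
    for ds in datasets:
        rec = ~ds.is_novel
        model = fit_dlda(ds.patterns[rec], ds.labels[rec])
        coords = project(model, ds.patterns)
        blocks = []   # (class_key, window, row indices)
        classes = np.unique(ds.labels[rec])
        if novelty_variant:
            classes = classes[:n_recurring_classes_novelty]
        for w in session_windows:
            in_w = ds.session == w
            if novelty_variant:
                pool = np.flatnonzero(ds.is_novel & in_w)
                take = min(n_novel_per_window, len(pool))
                if take == 0:
                    raise ValueError(f"no novel exemplars in session window {w}")
                blocks.append((NOVEL, w, rng.choice(pool, take, replace=False)))
            n_take = (n_recurring_per_class_novelty if novelty_variant
                      else n_per_class)
            for c in classes:
                pool = np.flatnonzero((ds.labels == c) & in_w)
                if len(pool) < n_take:
                    raise ValueError(
                        f"class {c} has {len(pool)} exemplars in session "
                        f"window {w}, need {n_take}")
                blocks.append((int(c), w, rng.choice(pool, n_take, replace=False)))
        rows = np.concatenate([b[2] for b in blocks])
        sub = coords[rows]
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(sub)) / np.sqrt(coords.shape[1])
        if annot is None:
            annot = pd.DataFrame({
                "class": np.concatenate([[b[0]] * len(b[2]) for b in blocks]),
                "window": np.concatenate([[b[1]] * len(b[2]) for b in blocks])})
        # average over recurring-class relabelings
        rec_block_ids = [i for i, b in enumerate(blocks) if b[0] != NOVEL]
        sizes = [len(b[2]) for b in blocks]
        starts = np.cumsum([0] + sizes)
        n_rows = starts[-1]
        Dbar = np.zeros_like(D)
        n_eff = max(n_label_perms, 1)
        uniq_rec = sorted({blocks[i][0] for i in rec_block_ids})
        for p in range(n_eff):
            if n_label_perms == 0:
                perm_map = {c: c for c in uniq_rec}
            else:
                shuffled = rng.permutation(uniq_rec)
                perm_map = dict(zip(uniq_rec, shuffled))
            order = np.arange(n_rows)
            # move each recurring block to the position of its permuted class
            pos_of = {(b[0], b[1]): i for i, b in enumerate(blocks)}
            for i, b in enumerate(blocks):
                if b[0] == NOVEL:
                    continue
                j = pos_of[(perm_map[b[0]], b[1])]
                order[starts[i]:starts[i] + sizes[i]] = np.arange(
                    starts[j], starts[j] + sizes[j])
            Dbar += D[np.ix_(order, order)]
        Dbar /= n_eff
        acc = Dbar if acc is None else acc + Dbar
    return acc / len(datasets), annot


def mds_embed(matrix: np.ndarray, dims: int = 2, rng_seed=0,
              n_init: int = 8, max_iter: int = 10_000, eps: float = 1e-12
              ) -> tuple[np.ndarray, float]:
    """Metric-stress MDS embedding of a distance matrix.

    Multiple random restarts, best (raw metric) stress kept.  Returns
    (coords, stress).
    """
    from sklearn.manifold import MDS

    D = np.asarray(matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    seed = (int(rng_seed.integers(2 ** 31)) if isinstance(rng_seed, np.random.Generator)
            else int(rng_seed))
    common = dict(n_components=dims, n_init=n_init, max_iter=max_iter, eps=eps,
                  random_state=seed, normalized_stress=False)
    try:
        mds = MDS(metric="precomputed", metric_mds=True, init="random", **common)
        coords = mds.fit_transform(D)
    except TypeError:    # older scikit-learn API
        mds = MDS(dissimilarity="precomputed", metric=True, **common)
        coords = mds.fit_transform(D)
    return coords, float(mds.stress_)


# ---------------------------------------------------------------------------
# pipeline

DEFAULT_CONFIG = {
    "seed": 0,
    "structure": "unstructured",
    "n_voxels": 30,
    "n_timepoints": 3,
    # gamma0 = 0.5 selectivity requires (1/2)^n <= alpha, i.e. >= 5 datasets
    "n_observers": 4,
    "n_conditions": 2,
    "n_repeats": 5,
    "n_perm": 200,
    "n_second": 10_000,
    "n_comparisons": 2,
    "gamma0": 0.5,
    "alpha": 0.05,
    "n_stability_reps": 100,
    "parcels": [{"parcel_id": "planted", "effect": True},
                {"parcel_id": "null", "effect": False}],
}


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> Path:
    """End-to-end smoke pipeline: simulate design and responses, run the
    cross-validated inference chain, batch trends and stability per parcel,
    and write all tables plus a manifest with seeds and versions."""
    from . import __version__
    from .design import DesignSpec, generate_experiment
    from .inference import CVScheme, analyze_parcel
    from .synth import GeneratorParams, ParcelSpec, make_multi_dataset
    from .trends import (fixed_subspace_coords, pseudo_run_baseline,
                         run_centroids)

    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_root = np.random.SeedSequence(cfg["seed"])
    design = DesignSpec(structure=cfg["structure"])
    seqs = generate_experiment(design, rng_seed=np.random.default_rng(
        seed_root.spawn(1)[0]))
    parcel = ParcelSpec(n_voxels=cfg["n_voxels"], n_timepoints=cfg["n_timepoints"])
    scheme = CVScheme(n_repeats=cfg["n_repeats"])
    manifest = {"version": __version__, "seed": cfg["seed"], "config": cfg,
                "stages": []}
    results = []
    for k, pc in enumerate(cfg["parcels"]):
        stage = f"parcel:{pc['parcel_id']}"
        try:
            pseed = seed_root.spawn(1)[0]
            datasets = make_multi_dataset(
                seqs, parcel, GeneratorParams(),
                n_observers=cfg["n_observers"], n_conditions=cfg["n_conditions"],
                effect_present=pc.get("effect", True), rng_seed=pseed)
            for ds in datasets:
                ds.parcel_id = pc["parcel_id"]
            res = analyze_parcel(datasets, scheme, n_perm=cfg["n_perm"],
                                 n_second=cfg["n_second"],
                                 n_comparisons=cfg["n_comparisons"],
                                 gamma0=cfg["gamma0"], alpha=cfg["alpha"],
                                 rng_seed=np.random.default_rng(seed_root.spawn(1)[0]))
            results.append(res)
            coords = fixed_subspace_coords(datasets[0])
            stab = pseudo_run_baseline(
                coords, datasets[0].labels, datasets[0].is_novel,
                datasets[0].run, n_rep=cfg["n_stability_reps"],
                rng_seed=np.random.default_rng(seed_root.spawn(1)[0]),
                observed=run_centroids(coords, datasets[0].labels,
                                       datasets[0].is_novel, datasets[0].run))
            stab.aggregate().to_csv(out / f"stability_{pc['parcel_id']}.csv",
                                    index=False)
            manifest["stages"].append({"stage": stage, "status": "ok"})
        except Exception as exc:
            manifest["stages"].append({"stage": stage, "status": "failed",
                                       "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc
    pd.DataFrame(results).to_csv(out / "prevalence_summary.csv", index=False)
    (out / "prevalence.json").write_text(json.dumps(results, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
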