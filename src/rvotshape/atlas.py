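"""Deformable-template (atlas) estimation for a registered population.

The template — the population mean shape — is estimated jointly with
per-subject momenta: each subject is represented as a diffeomorphic
deformation of the template, driven by momentum vectors at a sparse
control-point lattice and matched to the subject surface with a varifold
data term.  Estimation alternates momenta updates and template vertex
updates, run over a coarse-to-fine schedule of kernel widths
(`T0` = initial subject, `T1` after the first stage, `T2` after the last),
optionally followed by compactness-driven re-registration rounds (`T3`).

Exposed in the modelling style of statsmodels: ``AtlasModel`` holds the
data and configuration, ``fit`` returns an ``AtlasResults`` carrying the
template, momenta, convergence history and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .geometry import SurfaceMesh, SurfaceLocator
from .deformation import (
    FlowTape,
    flow,
    kernel_matrix,
    varifold_distance,
    varifold_repr,
    varifold_loss_grad,
    _inner,
)


@dataclass
class KernelConfig:
    """One stage of the multiscale schedule.

    sigma_def : deformation kernel width (mm) — spatial scale of the flow.
    sigma_var : varifold kernel width (mm) — spatial scale of the data term.
    n_control_side : control-point lattice density per axis (pruned to the
        surface neighbourhood).
    n_time_steps : Euler steps of the Hamiltonian integration.
    reg_weight : deformation-energy weight; ``None`` balances the data and
        regularity terms automatically at stage start.
    max_iter : momenta gradient-descent iterations per alternation.
    """

    sigma_def: float
    sigma_var: float
    n_control_side: int = 4
    n_time_steps: int = 10
    reg_weight: float | None = None
    max_iter: int = 40

    def __post_init__(self):
        if self.sigma_def <= 0 or self.sigma_var <= 0:
            raise ValueError("kernel widths must be positive")
        if self.n_time_steps < 1:
            raise ValueError("n_time_steps must be >= 1")


def default_schedule(diag: float, sizes=(0.4, 0.2, 0.1), lattice=(4, 6, 8)) -> list[KernelConfig]:
    """Coarse-to-fine schedule scaled to the template bounding-box diagonal."""
    return [
        KernelConfig(
            sigma_def=f * diag, sigma_var=0.5 * f * diag, n_control_side=nc
        )
        for f, nc in zip(sizes, lattice)
    ]


def _control_lattice(template: SurfaceMesh, cfg: KernelConfig) -> np.ndarray:
    """Regular lattice over the template bounds, pruned to the surface band."""
    lo = template.vertices.min(axis=0)
    hi = template.vertices.max(axis=0)
    pad = 0.05 * (hi - lo)
    axes = [np.linspace(lo[i] - pad[i], hi[i] + pad[i], cfg.n_control_side) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = SurfaceLocator(template).query(grid)[1]
    keep = grid[d <= cfg.sigma_def]
    return keep if len(keep) >= 4 else grid


def _auto_reg_weight(template: SurfaceMesh, controls: np.ndarray, targets, cfg) -> float:
    """Balance terms: probe deformation energy ~ 10% of the median data term."""
    d0 = np.median(
        [varifold_distance(template, t, cfg.sigma_var) for t in targets]
    )
    probe = np.ones_like(controls)  # 1 mm momenta everywhere
    K = kernel_matrix(controls, controls, cfg.sigma_def)
    e_probe = 0.5 * float(np.einsum("ij,id,jd->", K, probe, probe))
    if e_probe <= 0 or d0 <= 0:
        return 1e-6
    return 0.1 * d0 / e_probe


def _descend(x0, obj_grad, max_iter, tol=1e-5, step0=None):
    """Gradient descent with backtracking; returns (x, trace, aux_last)."""
    x = x0.copy()
    J, g, aux = obj_grad(x)
    trace = [J]
    step = step0 if step0 is not None else 1.0 / (np.linalg.norm(g) + 1e-12)
    for _ in range(max_iter):
        improved = False
        for _bt in range(20):
            x_try = x - step * g
            J_try, g_try, aux_try = obj_grad(x_try)
            if J_try < J:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        rel = (J - J_try) / (abs(J) + 1e-30)
        x, J, g, aux = x_try, J_try, g_try, aux_try
        trace.append(J)
        step *= 1.5
        if rel < tol:
            break
    return x, trace, aux


def match(
    template: SurfaceMesh,
    target: SurfaceMesh,
    kernel: KernelConfig,
    init_momenta: np.ndarray | None = None,
    control_points: np.ndarray | None = None,
    reg_weight: float | None = None,
):
    """Match a single target by deforming the template (momenta estimation).

    Returns ``(momenta, control_points, diagnostics)`` where diagnostics
    holds the final objective, the iteration trace and a convergence flag.
    """
    controls = (
        control_points
        if control_points is not None
        else _control_lattice(template, kernel)
    )
    lam = reg_weight
    if lam is None:
        lam = _auto_reg_weight(template, controls, [target], kernel)
    K = kernel_matrix(controls, controls, kernel.sigma_def)
    target_repr = varifold_repr(target.vertices, target.faces)
    const = _inner(*target_repr, *target_repr, kernel.sigma_var)

    def obj_grad(a_flat):
        a = a_flat.reshape(-1, 3)
        tape = FlowTape(
            template.vertices, controls, a, kernel.sigma_def, kernel.n_time_steps
        )
        loss, gv = varifold_loss_grad(
            tape.points, template.faces, target_repr, kernel.sigma_var
        )
        ga, _, _ = tape.backward(gv)
        Ka = K @ a
        J = loss + const + lam * 0.5 * float((a * Ka).sum())
        return J, (ga + lam * Ka).ravel(), None

    a0 = (
        np.zeros((len(controls), 3))
        if init_momenta is None
        else np.asarray(init_momenta, float)
    )
    a_fit, trace, _ = _descend(a0.ravel(), obj_grad, kernel.max_iter)
    converged = len(trace) < kernel.max_iter + 1 or (
        len(trace) > 1 and (trace[-2] - trace[-1]) / (abs(trace[-2]) + 1e-30) < 1e-3
    )
    if not converged:
        warnings.warn("momenta estimation did not converge; returning best")
    diagnostics = dict(objective=float(trace[-1]), trace=[float(t) for t in trace],
                       converged=bool(converged))
    return a_fit.reshape(-1, 3), controls, diagnostics


class AtlasModel:
    """Template-estimation model over a rigidly registered population.

    Parameters
    ----------
    meshes : list of SurfaceMesh (already rigidly aligned, common remeshing).
    subject_ids : optional labels, default S001..
    """

    def __init__(self, meshes, subject_ids=None):
        if not meshes:
            raise ValueError("empty population")
        self.meshes = list(meshes)
        self.subject_ids = list(subject_ids or [f"S{i+1:03d}" for i in range(len(meshes))])
        if len(self.subject_ids) != len(self.meshes):
            raise ValueError("subject_ids length mismatch")

    def initial_template_index(self) -> int:
        """Subject whose surface area is closest to the population mean."""
        sas = np.array([m.area for m in self.meshes])
        return int(np.argmin(np.abs(sas - sas.mean())))

    def fit(
        self,
        schedule: list[KernelConfig] | None = None,
        init_index: int | None = None,
        n_alternations: int = 2,
        template_steps: int = 8,
        verbose: bool = False,
    ) -> "AtlasResults":
        """Estimate the template and per-subject momenta over the schedule."""
        idx = self.initial_template_index() if init_index is None else init_index
        template = self.meshes[idx].copy()
        if schedule is None:
            schedule = default_schedule(template.bounding_box_diagonal())

        targets = [varifold_repr(m.vertices, m.faces) for m in self.meshes]

        history = []
        stage_labels = []
        controls = None
        momenta = None
        for s_idx, cfg in enumerate(schedule):
            controls = _control_lattice(template, cfg)
            momenta = np.zeros((len(self.meshes), len(controls), 3))
            consts = [_inner(x, N, x, N, cfg.sigma_var) for (x, N) in targets]
            lam = cfg.reg_weight
            if lam is None:
                lam = _auto_reg_weight(template, controls, self.meshes, cfg)
            K = kernel_matrix(controls, controls, cfg.sigma_def)
            stage_trace = []

            def subject_obj(a_flat, j, tmpl_v, tmpl_f):
                a = a_flat.reshape(-1, 3)
                tape = FlowTape(tmpl_v, controls, a, cfg.sigma_def, cfg.n_time_steps)
                loss, gv = varifold_loss_grad(
                    tape.points, tmpl_f, targets[j], cfg.sigma_var
                )
                ga, gy0, _ = tape.backward(gv)
                Ka = K @ a
                E = 0.5 * float((a * Ka).sum())
                J = loss + consts[j] + lam * E
                return J, (ga + lam * Ka).ravel(), gy0

            for alt in range(n_alternations):
                # (i) momenta update per subject
                total = 0.0
                for j in range(len(self.meshes)):
                    a_new, tr, _ = _descend(
                        momenta[j].ravel(),
                        lambda a, j=j: subject_obj(a, j, template.vertices, template.faces),
                        cfg.max_iter,
                    )
                    momenta[j] = a_new.reshape(-1, 3)
                    total += tr[-1]
                stage_trace.append(float(total))
                if verbose:
                    print(f"stage {s_idx} alt {alt} momenta: total={total:.4g}")

                # (ii) template vertex update with momenta fixed
                def template_obj(v_flat):
                    v = v_flat.reshape(-1, 3)
                    tot = 0.0
                    grad = np.zeros_like(v)
                    for j in range(len(self.meshes)):
                        J, _, gy0 = subject_obj(
                            momenta[j].ravel(), j, v, template.faces
                        )
                        tot += J
                        grad += gy0
                    return tot, grad.ravel(), None

                v_new, tr, _ = _descend(
                    template.vertices.ravel(), template_obj, template_steps
                )
                template = SurfaceMesh(
                    v_new.reshape(-1, 3),
                    template.faces.copy(),
                    dict(template.boundary_labels),
                )
                stage_trace.append(float(tr[-1]))
                if verbose:
                    print(f"stage {s_idx} alt {alt} template: total={tr[-1]:.4g}")

            # momenta centering: the mean momentum field is a deformation
            # every subject shares, i.e. a bias of the template away from
            # the population mean shape; transfer it onto the template
            a_mean = momenta.mean(axis=0)
            post_centering = None
            if np.linalg.norm(a_mean) > 1e-8:
                v_cent = flow(
                    template.vertices, controls, a_mean,
                    cfg.sigma_def, cfg.n_time_steps,
                )
                template = SurfaceMesh(
                    v_cent, template.faces.copy(), dict(template.boundary_labels)
                )
                momenta = momenta - a_mean
                total = 0.0
                for j in range(len(self.meshes)):
                    a_new, tr, _ = _descend(
                        momenta[j].ravel(),
                        lambda a, j=j: subject_obj(a, j, template.vertices, template.faces),
                        max(cfg.max_iter // 2, 5),
                    )
                    momenta[j] = a_new.reshape(-1, 3)
                    total += tr[-1]
                post_centering = float(total)
                if verbose:
                    print(f"stage {s_idx} post-centering: total={total:.4g}")
            history.append(dict(stage=s_idx, objective=stage_trace, lam=float(lam),
                                n_controls=len(controls),
                                post_centering=post_centering))
            stage_labels.append(f"T{min(s_idx + 1, 2)}")

        return AtlasResults(
            model=self,
            template=template,
            control_points=controls,
            momenta={sid: momenta[j] for j, sid in enumerate(self.subject_ids)},
            kernel=schedule[-1],
            schedule=schedule,
            history=history,
            stage_labels=["T0"] + stage_labels,
            init_index=idx,
        )


@dataclass
class AtlasResults:
    """Fitted atlas: template, control points, per-subject momenta."""

    model: AtlasModel
    template: SurfaceMesh
    control_points: np.ndarray
    momenta: dict
    kernel: KernelConfig
    schedule: list
    history: list
    stage_labels: list
    init_index: int

    def __post_init__(self):
        n_cp = len(self.control_points)
        for sid, a in self.momenta.items():
            if a.shape != (n_cp, 3):
                raise ValueError(f"momenta shape mismatch for {sid}")

    # -- reconstruction --------------------------------------------------
    def reconstruct(self, subject_id: str) -> SurfaceMesh:
        """Flow the template with a subject's momenta."""
        v = flow(
            self.template.vertices,
            self.control_points,
            self.momenta[subject_id],
            self.kernel.sigma_def,
            self.kernel.n_time_steps,
        )
        return SurfaceMesh(v, self.template.faces.copy(), dict(self.template.boundary_labels))

    def reconstruction_error(self):
        """Mean reconstructed-vertex-to-input-surface distance per subject.

        Returns (per-subject dict, median, IQR) in mm.
        """
        per = {}
        for j, sid in enumerate(self.model.subject_ids):
            rec = self.reconstruct(sid)
            d = SurfaceLocator(self.model.meshes[j]).query(rec.vertices)[1]
            per[sid] = float(d.mean())
        vals = np.array(list(per.values()))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return per, float(med), float(q3 - q1)

    def validate_template(self, summaries) -> dict:
        """Percent difference of SA, L_RVOT, D_AVE: template vs population mean.

        ``summaries`` is the list of per-subject GeometricSummary used for
        the population; the template is measured with the same pipeline.
        """
        from .centerline import compute_centreline
        from .measurements import geometric_summary

        cl = compute_centreline(self.template)
        ts = geometric_summary(self.template, cl)
        out = {}
        for name in ("sa", "l_rvot", "d_ave"):
            pop_mean = float(np.mean([getattr(s, name) for s in summaries]))
            out[name] = 100.0 * abs(getattr(ts, name) - pop_mean) / pop_mean
        return out

    def momenta_matrix(self) -> np.ndarray:
        """(n_subjects, n_controls*3) stacked flattened momenta."""
        return np.stack([self.momenta[sid].ravel() for sid in self.model.subject_ids])

    def summary(self) -> str:
        lines = [
            "Atlas estimation results",
            "=" * 40,
            f"subjects:        {len(self.model.subject_ids)}",
            f"template faces:  {len(self.template.faces)}",
            f"control points:  {len(self.control_points)}",
            f"stages:          {len(self.schedule)} "
            f"(sigma_def {', '.join(f'{c.sigma_def:.1f}' for c in self.schedule)} mm)",
        ]
        for h in self.history:
            obj = h["objective"]
            lines.append(
                f"stage {h['stage']}: objective {obj[0]:.4g} -> {obj[-1]:.4g}"
                f" ({h['n_controls']} controls, lambda={h['lam']:.3g})"
            )
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def save(self, directory) -> None:
        from pathlib import Path
        import pandas as pd
        from .meshops import write_mesh

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_mesh(self.template, d / "template.ply")
        pd.DataFrame(self.control_points, columns=["x", "y", "z"]).to_csv(
            d / "control_points.csv", index=False
        )
        rows = []
        for sid in self.model.subject_ids:
            for k, (mx, my, mz) in enumerate(self.momenta[sid]):
                rows.append(dict(subject_id=sid, control=k, mx=mx, my=my, mz=mz))
        pd.DataFrame(rows).to_csv(d / "momenta.csv", index=False)
        meta = dict(
            kernel=asdict(self.kernel),
            schedule=[asdict(c) for c in self.schedule],
            history=self.history,
            stage_labels=self.stage_labels,
            init_index=self.init_index,
            subject_ids=self.model.subject_ids,
            boundary_labels={int(k): v for k, v in self.template.boundary_labels.items()},
        )
        (d / "atlas.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_atlas(directory, meshes=None) -> AtlasResults:
    """Re-load a serialized atlas (optionally re-attaching the population)."""
    from pathlib import Path
    import pandas as pd
    from .meshops import read_mesh

    d = Path(directory)
    meta = yaml.safe_load((d / "atlas.yaml").read_text())
    template = read_mesh(d / "template.ply")
    template.boundary_labels = {
        int(k): v for k, v in (meta.get("boundary_labels") or {}).items()
    }
    controls = pd.read_csv(d / "control_points.csv")[["x", "y", "z"]].to_numpy()
    mom_df = pd.read_csv(d / "momenta.csv")
    momenta = {
        sid: g.sort_values("control")[["mx", "my", "mz"]].to_numpy()
        for sid, g in mom_df.groupby("subject_id")
    }
    model = AtlasModel(
        meshes if meshes is not None else [template] * len(meta["subject_ids"]),
        subject_ids=meta["subject_ids"],
    )
    kernel = KernelConfig(**meta["kernel"])
    schedule = [KernelConfig(**c) for c in meta["schedule"]]
    return AtlasResults(
        model=model,
        template=template,
        control_points=controls,
        momenta=momenta,
        kernel=kernel,
        schedule=schedule,
        history=meta["history"],
        stage_labels=meta["stage_labels"],
        init_index=meta["init_index"],
    )


# ----------------------------------------------------------------------
# compactness-driven re-registration and k-fold stability


def iterate_registration(
    shapes, centrelines, landmarks, results: AtlasResults,
    max_rounds: int = 3, m_modes: int | None = None,
    schedule=None, fit_kwargs=None,
):
    """Re-register the population to the template and refit while the
    model compactness improves; returns the atlas before the first decrease.

    ``shapes``/``centrelines``/``landmarks`` are the per-subject inputs in
    the current alignment; ``m_modes`` fixes the mode count of the
    compactness criterion (default: smallest count reaching 90% variance
    on the first fit).
    """
    from .shapemodes import ShapeModePCA
    from .centerline import compute_centreline
    from .measurements import extract_landmarks
    from .registration import register_population

    fit_kwargs = fit_kwargs or {}
    schedule = schedule or results.schedule

    def compactness_of(res):
        nonlocal m_modes
        pca = ShapeModePCA(res).fit()
        if m_modes is None:
            cum = np.cumsum(pca.variance_fraction)
            m_modes = int(np.searchsorted(cum, 0.9) + 1)
        m = min(m_modes, len(pca.variance_fraction))
        return float(np.sum(pca.variance_fraction[:m]))

    best = results
    best_c = compactness_of(results)
    log = [best_c]
    cur_shapes, cur_cls, cur_lms = list(shapes), list(centrelines), list(landmarks)
    for _ in range(max_rounds):
        tmpl_cl = compute_centreline(best.template)
        tmpl_lm = extract_landmarks(tmpl_cl)
        new_shapes, transforms = [], []
        for mesh, cl, lm in zip(cur_shapes, cur_cls, cur_lms):
            from .registration import register_subject

            T = register_subject(mesh, cl, lm, tmpl_cl, tmpl_lm, best.template)
            new_shapes.append(T.apply_mesh(mesh))
            new_shapes[-1].boundary_labels = dict(mesh.boundary_labels)
            transforms.append(T)
        cur_cls = [cl.transformed(T.rotation, T.translation) for cl, T in zip(cur_cls, transforms)]
        cur_lms = [lm.transformed(T.rotation, T.translation) for lm, T in zip(cur_lms, transforms)]
        cur_shapes = new_shapes
        model = AtlasModel(cur_shapes, subject_ids=best.model.subject_ids)
        res = model.fit(schedule=schedule, **fit_kwargs)
        c = compactness_of(res)
        log.append(c)
        if c <= best_c:
            break
        best, best_c = res, c
    best.compactness_log = log
    best.stage_labels = list(best.stage_labels) + ["T3"]
    return best


def kfold_template_stability(
    model: AtlasModel, results: AtlasResults, k: int = 9, seed: int = 0,
    schedule=None, fit_kwargs=None,
) -> np.ndarray:
    """Leave-one-fold-out template stability.

    The population is partitioned into ``k`` seeded folds (each subject
    left out exactly once); the template is recomputed without each fold
    and compared to the full template by mean corresponding-vertex
    distance (same topology).  Returns the k distances in mm.
    """
    n = len(model.meshes)
    if k > n:
        raise ValueError("k must not exceed the population size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [order[i::k] for i in range(k)]
    fit_kwargs = fit_kwargs or {}
    schedule = schedule or results.schedule
    dists = []
    for fold in folds:
        keep = sorted(set(range(n)) - set(int(i) for i in fold))
        sub = AtlasModel(
            [model.meshes[i] for i in keep],
            subject_ids=[model.subject_ids[i] for i in keep],
        )
        # keep the same initial template subject when it survives the fold
        init = None
        if results.init_index in keep:
            init = keep.index(results.init_index)
        res = sub.fit(schedule=schedule, init_index=init, **fit_kwargs)
        if res.template.vertices.shape == results.template.vertices.shape:
            d = np.linalg.norm(res.template.vertices - results.template.vertices, axis=1)
            dists.append(float(d.mean()))
        else:  # different T0 topology: fall back to surface distance
            d = SurfaceLocator(results.template).query(res.template.vertices)[1]
            dists.append(float(d.mean()))
    return np.asarray(dists)
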