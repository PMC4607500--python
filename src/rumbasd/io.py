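"""NIfTI/FSL readers and writers, run configuration and the end-to-end runner."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .deconv import DampingOptions, DeconvResult, SolverOptions, drl_sd, rumba_sd
from .kernel import (
    AcquisitionScheme,
    DiffusivityProfile,
    KernelDictionary,
    build_dictionary,
    make_sphere_grid,
)
from .metrics import MetricsReport, evaluate_field, extract_peaks
from .noise import contaminate, make_sensitivity_maps
from .phantoms import PhantomSpec, default_scheme

__all__ = ["RunConfig", "read_dwi", "write_outputs", "run_experiment"]


def read_dwi(data_path, bvals_path, bvecs_path, mask_path=None):
    """Load a 4-D DWI volume with its FSL gradient table and optional mask.

    Returns ``(data, scheme, mask, affine)``; the affine is preserved so
    outputs can be written back into the same space.  Raises a
    descriptive error when the gradient table length does not match the
    number of volumes.
    """
    img = nib.load(str(data_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    scheme = AcquisitionScheme.from_fsl(bvals_path, bvecs_path)
    if scheme.n_measurements != data.shape[-1]:
        raise ValueError(
            f"gradient table lists {scheme.n_measurements} measurements but "
            f"the volume contains {data.shape[-1]}"
        )
    mask = None
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.get_fdata()) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {data.shape[:3]}"
            )
    return data, scheme, mask, img.affine


def _save_nifti(path, array, affine):
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def write_outputs(result: DeconvResult, dictionary: KernelDictionary, out_dir,
                  affine=None, provenance=None, report: MetricsReport | None = None):
    """Write the solver outputs of one run to ``out_dir``.

    Files: ``fodf.nii.gz`` (M+2 volumes), ``sigma2.nii.gz``,
    ``peaks.nii.gz`` (4 directions x 3 components + 4 amplitudes),
    ``directions.txt`` (grid table), ``provenance.json`` and, when a
    metrics report is given, ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    _save_nifti(out / "fodf.nii.gz", result.fodf.coefficients, affine)
    _save_nifti(out / "sigma2.nii.gz", result.sigma2, affine)

    grid = dictionary.grid
    shape = result.fodf.coefficients.shape[:3]
    peaks_vol = np.zeros(shape + (16,))
    for idx in zip(*np.nonzero(result.mask)):
        ps = extract_peaks(result.fodf.coefficients[idx], grid)
        k = ps.count
        peaks_vol[idx][: 3 * k] = ps.directions.ravel()
        peaks_vol[idx][12 : 12 + k] = ps.amplitudes
    _save_nifti(out / "peaks.nii.gz", peaks_vol, affine)

    dictionary.export_directions(out / "directions.txt")
    with open(out / "iterations.log", "w") as fh:
        for entry in result.log:
            fh.write(
                f"iter={entry['iteration']} nll={entry['nll']:.10g} "
                f"mean_alpha={entry['mean_alpha']:.10g}\n"
            )
    prov = dict(provenance or {})
    if result.options is not None:
        prov.setdefault("method_options", dataclasses.asdict(result.options))
    prov.setdefault("grid", dict(dictionary.grid.metadata))
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    if report is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one phantom -> noise -> fit -> evaluate run."""

    family: str = "crossing_angle"
    angle: float = 70.0
    minor_fraction: float = 0.5
    shape: tuple = (12, 12, 12)
    snr: float = 15.0
    combiner: str = "smf"
    n_coils: int = 8
    rho: float = 0.05
    method: str = "rumba"               # rumba | drl
    noise_family: str = "rician"
    tv_mode: str = "none"
    iterations: int = 200
    normalize: bool | None = None
    target_m: int = 724
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["shape"] = list(self.shape)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["shape"] = tuple(payload["shape"])
        if payload.get("normalize") is not None:
            payload["normalize"] = bool(payload["normalize"])
        return cls(**payload)


def run_experiment(config: RunConfig, dictionary: KernelDictionary | None = None):
    """Generate a phantom, contaminate it, fit and evaluate, end to end.

    Returns ``(report, result, phantom)``.  The report's ``extra`` dict
    carries the estimated vs true noise variance and the run seed.  A
    prebuilt dictionary may be passed to amortize its construction over
    several runs.
    """
    spec = PhantomSpec(
        family=config.family,
        shape=tuple(config.shape),
        angle=config.angle if config.family == "crossing_angle" else None,
        minor_fraction=(
            config.minor_fraction if config.family == "volume_fraction" else None
        ),
    )
    phantom = spec.build()
    maps = make_sensitivity_maps(config.n_coils, tuple(config.shape))
    noisy, provenance = contaminate(
        phantom.signal,
        snr=config.snr,
        combiner=config.combiner,
        n_coils=config.n_coils,
        rho=config.rho,
        seed=config.seed,
        sensitivity_maps=maps,
    )
    if dictionary is None:
        grid = make_sphere_grid(config.target_m)
        dictionary = build_dictionary(phantom.scheme, grid, phantom.profile)
    options = SolverOptions(
        noise_family=config.noise_family if config.method == "rumba" else "gaussian",
        n_coils=float(config.n_coils),
        iterations=config.iterations,
        tv_mode=config.tv_mode,
        normalize=config.normalize,
        log_every=max(1, config.iterations // 20),
    )
    if config.method == "rumba":
        result = rumba_sd(noisy, dictionary, options)
    elif config.method == "drl":
        result = drl_sd(noisy, dictionary, DampingOptions(), options)
    else:
        raise ValueError(f"unknown method {config.method!r}")

    eval_mask = phantom.truth.count >= 1
    coeffs = result.fodf.coefficients[eval_mask]
    truths = [phantom.truth.voxel(idx) for idx in zip(*np.nonzero(eval_mask))]
    totals = coeffs.sum(axis=1)
    wm_fractions = np.divide(
        coeffs[:, : dictionary.grid.m].sum(axis=1),
        totals,
        out=np.ones_like(totals),
        where=totals > 0,
    )
    report = evaluate_field(coeffs, dictionary.grid, truths, wm_fractions)

    cross = phantom.truth.count == 2
    if cross.any():
        ccoeffs = result.fodf.coefficients[cross]
        ctruths = [phantom.truth.voxel(idx) for idx in zip(*np.nonzero(cross))]
        ctotals = ccoeffs.sum(axis=1)
        cwm = np.divide(
            ccoeffs[:, : dictionary.grid.m].sum(axis=1),
            ctotals,
            out=np.ones_like(ctotals),
            where=ctotals > 0,
        )
        creport = evaluate_field(ccoeffs, dictionary.grid, ctruths, cwm)
        report.extra["crossing"] = creport.to_dict()

    sigma_true = provenance["sigma"]
    # variance actually present in the combined magnitude image: for the
    # matched filter with normalized maps it is sigma^2[(1-rho) + rho (sum C)^2]
    if config.combiner == "smf":
        s1 = maps.sum(axis=0)
        eff = sigma_true**2 * ((1.0 - config.rho) + config.rho * s1**2)
    else:
        eff = np.full(tuple(config.shape), sigma_true**2)
    est = result.sigma2[result.mask & eval_mask]
    report.extra.update(
        seed=config.seed,
        sigma2_true=float(sigma_true**2),
        sigma2_true_effective=float(eff[eval_mask].mean()),
        sigma2_estimated=float(est.mean()) if est.size else float("nan"),
        provenance=provenance,
    )
    return report, result, phantom
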