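"""Dataset and ensemble persistence plus validated run configuration.

Molecular datasets travel as extended XYZ (per-frame comment line carrying
the adiabatic energies as ``E0=... E1=...`` fields); abstract model
datasets as CSV with columns ``x1..xd, E1..En``. Fitted surrogate
ensembles serialize to a single NumPy archive with a JSON metadata record
and a format-version field. Run configuration is a YAML document validated
into typed blocks; unknown keys are rejected by name.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cp import PotentialSample
from .descriptors import DescriptorConfig
from .krr import HyperparamPolicy, KernelModel, SurrogateEnsemble
from .models import SampledDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_ensemble",
    "load_ensemble",
    "RunConfig",
    "load_config",
]

ENSEMBLE_FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# datasets


def write_dataset(dataset: SampledDataset, path: str | Path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        d, n = dataset.dim, dataset.n_states
        cols = [f"x{i + 1}" for i in range(d)] + [f"E{i + 1}" for i in range(n)]
        data = np.hstack([dataset.coords_matrix(), dataset.energies_matrix()])
        pd.DataFrame(data, columns=cols).to_csv(path, index=False)
    elif fmt == "extxyz":
        if dataset.elements is None:
            raise ValueError("extxyz output requires element labels on the dataset")
        lines = []
        n_atoms = len(dataset.elements)
        for s in dataset.samples:
            if s.coords.size != 3 * n_atoms:
                raise ValueError("extxyz output requires 3N Cartesian coordinates")
            efields = " ".join(f"E{i}={float(e)!r}" for i, e in enumerate(s.energies))
            lines.append(str(n_atoms))
            lines.append(f"Properties=species:S:1:pos:R:3 {efields}")
            pos = s.coords.reshape(n_atoms, 3)
            for el, p in zip(dataset.elements, pos):
                lines.append(f"{el} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dataset format {fmt!r}")


def _parse_extxyz(text: str, path: Path) -> SampledDataset:
    lines = text.splitlines()
    samples: list[PotentialSample] = []
    elements: list[str] | None = None
    i = 0
    frame = 0
    n_states: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + n_atoms >= len(lines) + 1 and n_atoms > 0:
            raise ValueError(f"{path}: frame {frame} is truncated")
        comment = lines[i + 1]
        efields = {}
        for tok in comment.split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                if k.startswith("E") and k[1:].isdigit():
                    efields[int(k[1:])] = float(v)
        if not efields:
            raise ValueError(f"{path}:{i + 2}: frame {frame} has no E0=,E1=,... fields")
        energies = np.array([efields[k] for k in sorted(efields)])
        if n_states is None:
            n_states = energies.size
        elif energies.size != n_states:
            raise ValueError(
                f"{path}:{i + 2}: frame {frame} has {energies.size} energies, "
                f"expected {n_states}"
            )
        frame_elements = []
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + a}: malformed atom line")
            frame_elements.append(parts[0])
            coords[a] = [float(p) for p in parts[1:4]]
        if elements is None:
            elements = frame_elements
        elif frame_elements != elements:
            raise ValueError(f"{path}: frame {frame} changes the element list")
        if np.any(np.diff(energies) < 0):
            warnings.warn(f"frame {frame}: energies were not ascending; re-sorted")
            energies = np.sort(energies)
        samples.append(PotentialSample(coords=coords.ravel(), energies=energies))
        i += 2 + n_atoms
    if not samples:
        raise ValueError(f"{path}: empty dataset")
    return SampledDataset(
        samples=samples, provenance={"source": str(path)}, elements=elements
    )


def read_dataset(path: str | Path, fmt: str = "csv") -> SampledDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "extxyz":
        return _parse_extxyz(path.read_text(), path)
    if fmt != "csv":
        raise ValueError(f"unknown dataset format {fmt!r}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    xcols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    ecols = [c for c in df.columns if c.startswith("E") and c[1:].isdigit()]
    xcols.sort(key=lambda c: int(c[1:]))
    ecols.sort(key=lambda c: int(c[1:]))
    if not xcols or not ecols:
        raise ValueError(f"{path}: need x1..xd and E1..En columns")
    coords = df[xcols].to_numpy(float)
    energies = df[ecols].to_numpy(float)
    if np.any(np.diff(energies, axis=1) < 0):
        warnings.warn(f"{path}: some rows had unsorted energies; re-sorted")
        energies = np.sort(energies, axis=1)
    samples = [
        PotentialSample(coords=c, energies=e) for c, e in zip(coords, energies)
    ]
    return SampledDataset(samples=samples, provenance={"source": str(path)})


# --------------------------------------------------------------------------
# ensembles


def save_ensemble(ensemble: SurrogateEnsemble, path: str | Path) -> None:
    """Serialize a fitted ensemble to a single ``.npz`` archive."""
    meta = {
        "format_version": ENSEMBLE_FORMAT_VERSION,
        "mode": ensemble.mode,
        "n_states": ensemble.n_states,
        "elements": ensemble.elements,
        "descriptor": {
            "mode": ensemble.descriptor.mode,
            "r_cut": ensemble.descriptor.r_cut,
            "n_max": ensemble.descriptor.n_max,
            "l_max": ensemble.descriptor.l_max,
            "sigma_atom": ensemble.descriptor.sigma_atom,
            "species": list(ensemble.descriptor.species),
            "reduction": ensemble.descriptor.reduction,
        },
        "fields": {
            label: {
                "kernel": m.kernel,
                "lengthscale": m.lengthscale,
                "regularization": m.regularization,
            }
            for label, m in ensemble.models.items()
        },
    }
    arrays = {"metadata": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for label, m in ensemble.models.items():
        arrays[f"x_train__{label}"] = m.x_train
        arrays[f"alpha__{label}"] = m.alpha
    np.savez(Path(path), **arrays)


def load_ensemble(path: str | Path) -> SurrogateEnsemble:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as archive:
        try:
            meta = json.loads(bytes(archive["metadata"]).decode())
        except (KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: corrupted or missing ensemble metadata") from exc
        version = meta.get("format_version")
        if not isinstance(version, int) or version < 1:
            raise ValueError(f"{path}: invalid format_version {version!r}")
        if version > ENSEMBLE_FORMAT_VERSION:
            raise ValueError(
                f"{path}: ensemble format version {version} is newer than the "
                f"supported version {ENSEMBLE_FORMAT_VERSION}; upgrade the package"
            )
        required = {"mode", "n_states", "descriptor", "fields"}
        if not required <= meta.keys():
            raise ValueError(f"{path}: metadata is missing {required - meta.keys()}")
        descriptor = DescriptorConfig(
            mode=meta["descriptor"]["mode"],
            r_cut=meta["descriptor"]["r_cut"],
            n_max=meta["descriptor"]["n_max"],
            l_max=meta["descriptor"]["l_max"],
            sigma_atom=meta["descriptor"]["sigma_atom"],
            species=tuple(meta["descriptor"]["species"]),
            reduction=meta["descriptor"]["reduction"],
        )
        models = {}
        for label, f in meta["fields"].items():
            try:
                x_train = archive[f"x_train__{label}"]
                alpha = archive[f"alpha__{label}"]
            except KeyError as exc:
                raise ValueError(f"{path}: missing arrays for field {label!r}") from exc
            models[label] = KernelModel(
                kernel=f["kernel"],
                lengthscale=f["lengthscale"],
                regularization=f["regularization"],
                x_train=x_train,
                alpha=alpha,
                target_label=label,
            )
    return SurrogateEnsemble(
        mode=meta["mode"],
        n_states=meta["n_states"],
        descriptor=descriptor,
        models=models,
        elements=meta.get("elements"),
    )


# --------------------------------------------------------------------------
# run configuration


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Block):
    """Analytic model to simulate from (two-state cone or random LVC)."""

    type: str = "first_order_two_state"  # or "random_linear_vibronic"
    g_norm: float = 0.5
    h_norm: float = 0.5
    s_x: float = 0.25
    s_y: float = 0.1
    n_states: int = 2
    dim: int = 2
    branching_rank: int = 2


class DescriptorBlock(_Block):
    mode: str = "raw"
    r_cut: float = 5.0
    n_max: int = 6
    l_max: int = 4
    sigma_atom: float = 0.5
    species: list[str] = Field(default_factory=list)
    reduction: str = "average"

    def to_config(self) -> DescriptorConfig:
        return DescriptorConfig(
            mode=self.mode,
            r_cut=self.r_cut,
            n_max=self.n_max,
            l_max=self.l_max,
            sigma_atom=self.sigma_atom,
            species=tuple(self.species),
            reduction=self.reduction,
        )


class KernelBlock(_Block):
    kind: str = "rbf"
    lengthscale: float | None = None
    regularization: float | None = None
    lengthscale_grid: list[float] = Field(
        default_factory=lambda: [0.03, 0.1, 0.3, 1.0, 3.0]
    )
    regularization_grid: list[float] = Field(
        default_factory=lambda: [1e-12, 1e-10, 1e-8, 1e-6]
    )
    folds: int = 5
    seed: int = 0

    def to_policy(self) -> HyperparamPolicy:
        return HyperparamPolicy(
            kernel=self.kind,
            lengthscale=self.lengthscale,
            regularization=self.regularization,
            lengthscale_grid=tuple(self.lengthscale_grid),
            regularization_grid=tuple(self.regularization_grid),
            k_folds=self.folds,
            seed=self.seed,
        )


class SamplingBlock(_Block):
    bounds: list[float] = Field(default_factory=lambda: [-0.25, 0.25])
    n_samples: int = 2000
    seed: int = 0


class AnalysisBlock(_Block):
    step: float | None = None  # None → per-object default
    threshold: float = 1e-2


class PathsBlock(_Block):
    dataset: str | None = None
    ensemble: str | None = None
    output: str | None = None


class RunConfig(_Block):
    mode: str = "omega_cp"
    n_states: int = 2
    model: ModelBlock = Field(default_factory=ModelBlock)
    descriptor: DescriptorBlock = Field(default_factory=DescriptorBlock)
    kernel: KernelBlock = Field(default_factory=KernelBlock)
    sampling: SamplingBlock = Field(default_factory=SamplingBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)
    paths: PathsBlock = Field(default_factory=PathsBlock)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are named."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
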