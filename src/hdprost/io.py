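"""HDF5 dataset container, NIfTI map output, CSV trains, dictionary persistence.

HDF5 layout (complex arrays as paired real/imag float64 datasets, portable
across languages):

    /kspace/{real,imag}        Z x L x Nc
    /sampling/mask             Mx x My (x Mz) x L, uint8           (Cartesian)
    /sampling/traj             Z x 2 float64, cycles/pixel         (radial)
    /sampling/spoke_of_sample  Z int                               (radial)
    /sampling/time_point       Z int                               (radial)
    /sens/{real,imag}          Mx x My (x Mz) x Nc
    /sequence/fa_deg, rf_phase_deg, @tr_ms, @te_ms, @inversion     (optional)
    /truth/*                   ground-truth maps (optional)
    /meta  @matrix, @mode, @seed, ...

Parameter maps are written as NIfTI volumes (T1 and T2 in milliseconds, M0 as
magnitude).
"""

from __future__ import annotations

import numpy as np

import h5py
import nibabel as nib

from .encoding import CartesianSampling, RadialSampling
from .mrf import MRFDictionary, ParameterMaps, SequenceParams
from .synthetic import DatasetContainer


class FormatError(ValueError):
    """The file does not follow the container layout."""


class DimensionError(ValueError):
    """Declared array dimensions are mutually inconsistent."""


def _write_complex(group, name, arr):
    group.create_dataset(f"{name}/real", data=np.ascontiguousarray(arr.real))
    group.create_dataset(f"{name}/imag", data=np.ascontiguousarray(arr.imag))


def _read_complex(group, name):
    if name not in group or "real" not in group[name]:
        raise FormatError(f"missing complex group /{group.name.strip('/')}/{name}".replace("//", "/"))
    return group[name]["real"][...] + 1j * group[name]["imag"][...]


def save_dataset(ds: DatasetContainer, path) -> None:
    """Write a :class:`DatasetContainer` to the HDF5 layout above."""
    radial = isinstance(ds.sampling, RadialSampling)
    kspace = ds.kspace
    if radial:
        k3 = kspace[:, None, :] if kspace.ndim == 2 else kspace
    else:
        L, nc = kspace.shape[-2:]
        k3 = kspace.reshape(-1, L, nc)
    with h5py.File(path, "w") as f:
        _write_complex(f, "kspace", k3)
        samp = f.create_group("sampling")
        if radial:
            samp.create_dataset("traj", data=ds.sampling.coords)
            samp.create_dataset("spoke_of_sample", data=ds.sampling.spoke_of_sample)
            samp.create_dataset("time_point", data=ds.sampling.time_point)
            samp.attrs["samples_per_spoke"] = ds.sampling.samples_per_spoke
        else:
            samp.create_dataset("mask", data=ds.sampling.masks.astype(np.uint8))
        _write_complex(f, "sens", ds.sens)
        if ds.sequence is not None:
            g = f.create_group("sequence")
            g.create_dataset("fa_deg", data=ds.sequence.fa_deg)
            g.create_dataset("rf_phase_deg", data=ds.sequence.rf_phase_deg)
            g.attrs["tr_ms"] = ds.sequence.tr_ms
            g.attrs["te_ms"] = ds.sequence.te_ms
            g.attrs["inversion"] = np.uint8(ds.sequence.invert)
        if ds.truth:
            g = f.create_group("truth")
            for key, val in ds.truth.items():
                val = np.asarray(val)
                if np.iscomplexobj(val):
                    _write_complex(g, key, val)
                else:
                    g.create_dataset(key, data=val)
        meta = f.create_group("meta")
        meta.attrs["mode"] = ds.mode
        for key, val in ds.meta.items():
            meta.attrs[key] = val


def load_dataset(path) -> DatasetContainer:
    """Read a container back; validates shape consistency across groups."""
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise FormatError("missing /kspace")
        kspace = _read_complex(f, "kspace")
        if "sampling" not in f:
            raise FormatError("missing /sampling")
        samp = f["sampling"]
        if "sens" not in f:
            raise FormatError("missing /sens")
        sens = _read_complex(f, "sens")
        mode = f["meta"].attrs.get("mode", "") if "meta" in f else ""

        if "traj" in samp:
            sampling = RadialSampling(
                coords=samp["traj"][...],
                spoke_of_sample=samp["spoke_of_sample"][...],
                time_point=samp["time_point"][...],
                samples_per_spoke=int(samp.attrs["samples_per_spoke"]),
            )
            if kspace.shape[0] != sampling.n_samples:
                raise DimensionError(
                    f"kspace rows {kspace.shape[0]} != trajectory samples "
                    f"{sampling.n_samples}"
                )
            kspace = kspace[:, 0, :]
            mode = mode or "radial-mrf"
        elif "mask" in samp:
            masks = samp["mask"][...]
            sampling = CartesianSampling(masks=masks)
            spatial = masks.shape[:-1]
            L = masks.shape[-1]
            if kspace.shape[0] != int(np.prod(spatial)) or kspace.shape[1] != L:
                raise DimensionError(
                    f"kspace {kspace.shape} inconsistent with mask {masks.shape}"
                )
            kspace = kspace.reshape(spatial + kspace.shape[1:])
            if sens.shape[:-1] != spatial:
                raise DimensionError(
                    f"sens {sens.shape} inconsistent with mask {masks.shape}"
                )
            mode = mode or "cartesian-multicontrast"
        else:
            raise FormatError("/sampling holds neither mask nor traj")
        if kspace.shape[-1] != sens.shape[-1]:
            raise DimensionError(
                f"coil counts disagree: kspace {kspace.shape[-1]}, sens {sens.shape[-1]}"
            )
        if not np.any(sens):
            raise DimensionError("sensitivities are zero everywhere")

        sequence = None
        if "sequence" in f:
            g = f["sequence"]
            sequence = SequenceParams(
                fa_deg=g["fa_deg"][...],
                tr_ms=float(g.attrs["tr_ms"]),
                te_ms=float(g.attrs["te_ms"]),
                invert=bool(g.attrs["inversion"]),
                rf_phase_deg=g["rf_phase_deg"][...] if "rf_phase_deg" in g else None,
            )
        truth = {}
        if "truth" in f:
            for key in f["truth"]:
                node = f["truth"][key]
                if isinstance(node, h5py.Group):
                    truth[key] = _read_complex(f["truth"], key)
                else:
                    truth[key] = node[...]
        meta = dict(f["meta"].attrs) if "meta" in f else {}
        meta.pop("mode", None)
    return DatasetContainer(kspace=kspace, sampling=sampling, sens=sens,
                            mode=mode, sequence=sequence, truth=truth, meta=meta)


# ---------------------------------------------------------------------------
# parameter maps
# ---------------------------------------------------------------------------

def save_maps(maps: ParameterMaps, prefix) -> list:
    """Write T1/T2 (ms) and M0 magnitude as NIfTI volumes ``<prefix>_{t1,t2,m0}.nii.gz``."""
    mask = maps.mask.astype(bool)
    written = []
    for name, vol in (("t1", maps.t1_ms), ("t2", maps.t2_ms),
                      ("m0", np.abs(maps.m0))):
        if mask.any() and not np.all(np.isfinite(np.asarray(vol)[mask])):
            raise ValueError(f"non-finite {name} values inside the mask")
        data = np.where(mask, vol, 0.0).astype(np.float32)
        if data.ndim == 2:
            data = data[..., None]
        path = f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
        written.append(path)
    return written


def load_map(path) -> np.ndarray:
    return np.asanyarray(nib.load(path).dataobj)


def save_images(images: np.ndarray, path, meta: dict | None = None) -> None:
    """Reconstructed complex image stack to HDF5 (/images/{real,imag})."""
    with h5py.File(path, "w") as f:
        _write_complex(f, "images", np.asarray(images, dtype=np.complex128))
        g = f.create_group("meta")
        for key, val in (meta or {}).items():
            g.attrs[key] = val


def load_images(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return _read_complex(f, "images")


# ---------------------------------------------------------------------------
# flip-angle trains and dictionaries
# ---------------------------------------------------------------------------

def save_train_csv(fa_deg, path) -> None:
    """One flip angle per line, degrees."""
    np.savetxt(path, np.asarray(fa_deg, dtype=np.float64), fmt="%.6f")


def load_train_csv(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.float64, ndmin=1)


def save_dictionary(d: MRFDictionary, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("dict")
        _write_complex(g, "atoms", d.atoms)
        g.create_dataset("t1_grid", data=d.t1_ms)
        g.create_dataset("t2_grid", data=d.t2_ms)
        g.create_dataset("norms", data=d.norms)
        if d.basis is not None:
            _write_complex(g, "basis", d.basis.ur)
        if d.sequence is not None:
            g.create_dataset("fa_deg", data=d.sequence.fa_deg)
            g.create_dataset("rf_phase_deg", data=d.sequence.rf_phase_deg)
            g.attrs["tr_ms"] = d.sequence.tr_ms
            g.attrs["te_ms"] = d.sequence.te_ms
            g.attrs["inversion"] = np.uint8(d.sequence.invert)


def load_dictionary(path) -> MRFDictionary:
    from .encoding import SubspaceBasis

    with h5py.File(path, "r") as f:
        if "dict" not in f:
            raise FormatError("missing /dict")
        g = f["dict"]
        atoms = _read_complex(g, "atoms")
        basis = SubspaceBasis(_read_complex(g, "basis")) if "basis" in g else None
        sequence = None
        if "fa_deg" in g:
            sequence = SequenceParams(
                fa_deg=g["fa_deg"][...], tr_ms=float(g.attrs["tr_ms"]),
                te_ms=float(g.attrs["te_ms"]), invert=bool(g.attrs["inversion"]),
                rf_phase_deg=g["rf_phase_deg"][...] if "rf_phase_deg" in g else None,
            )
        return MRFDictionary(atoms=atoms, t1_ms=g["t1_grid"][...],
                             t2_ms=g["t2_grid"][...], norms=g["norms"][...],
                             sequence=sequence, basis=basis)
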