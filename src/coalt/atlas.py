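"""Domain types for parcellated cortical maps and matrices.

Everything downstream operates on a fixed cortical parcellation (by default the
68-parcel Desikan-Killiany atlas, 34 parcels per hemisphere). Parcel order is
frozen inside :class:`AtlasMetadata`; all loaders reorder their input to that
order so that vectors and matrices are always positionally aligned.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

import numpy as np

CYTO_CLASSES = ("agranular", "frontal", "parietal", "polar", "granular")

_PREFIX_RE = re.compile(r"^(lh|rh|l|r)[_.](.+)$", re.IGNORECASE)


def canonical_parcel_id(label: str) -> str:
    """Normalize a parcel label to canonical FreeSurfer style.

    Accepts the common naming dialects (``lh_bankssts``, ``L_bankssts``,
    ``LH.bankssts``) and returns ``lh_bankssts``. Labels without a
    recognizable hemisphere prefix are returned lower-cased and stripped.
    """
    label = label.strip()
    m = _PREFIX_RE.match(label)
    if m is None:
        return label.lower()
    hemi = m.group(1).lower()
    hemi = {"l": "lh", "r": "rh"}.get(hemi, hemi)
    return f"{hemi}_{m.group(2)}"


@dataclass(frozen=True)
class AtlasMetadata:
    """Parcellation metadata: labels, hemispheres, spherical centroids, cytoarchitecture.

    Parameters
    ----------
    parcel_id : array of str
        Ordered unique canonical labels, e.g. ``lh_bankssts``.
    hemisphere : array of {'L', 'R'}
        Hemisphere per parcel; counts must be equal.
    centroid : (n, 3) array
        Unit-norm parcel centroid directions on the sphere.
    cyto_class : array of str or None
        von Economo-Koskinas class per parcel (one of ``CYTO_CLASSES``),
        or None when histological labels are unavailable.
    """

    parcel_id: np.ndarray
    hemisphere: np.ndarray
    centroid: np.ndarray
    cyto_class: np.ndarray | None = None

    def __post_init__(self):
        pid = np.asarray(self.parcel_id, dtype=object)
        hemi = np.asarray(self.hemisphere, dtype=object)
        cen = np.asarray(self.centroid, dtype=float)
        object.__setattr__(self, "parcel_id", pid)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "centroid", cen)
        n = pid.size
        if len(set(pid)) != n:
            raise ValueError("parcel_ids must be unique")
        if hemi.shape != (n,) or not set(hemi) <= {"L", "R"}:
            raise ValueError("hemisphere must be 'L'/'R' per parcel")
        if int(np.sum(hemi == "L")) != int(np.sum(hemi == "R")):
            raise ValueError("parcel count must be equal per hemisphere")
        if cen.shape != (n, 3):
            raise ValueError(f"centroid must be ({n}, 3)")
        norms = np.linalg.norm(cen, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must be unit-norm within 1e-9")
        if self.cyto_class is not None:
            cc = np.asarray(self.cyto_class, dtype=object)
            object.__setattr__(self, "cyto_class", cc)
            if cc.shape != (n,) or not set(cc) <= set(CYTO_CLASSES):
                raise ValueError(f"cyto_class entries must be in {CYTO_CLASSES}")

    @property
    def n_parcels(self) -> int:
        return self.parcel_id.size

    def index_of(self, labels) -> np.ndarray:
        """Positions of ``labels`` (any dialect) in atlas order."""
        lookup = {p: i for i, p in enumerate(self.parcel_id)}
        idx = []
        for lab in labels:
            key = canonical_parcel_id(str(lab))
            if key not in lookup:
                raise KeyError(f"unknown parcel_id: {lab!r}")
            idx.append(lookup[key])
        return np.asarray(idx, dtype=int)

    def hash(self) -> str:
        """Stable identity of the atlas (labels + centroids), for spin-ensemble checks."""
        h = hashlib.sha256()
        h.update("|".join(map(str, self.parcel_id)).encode())
        h.update(np.round(self.centroid, 12).tobytes())
        return h.hexdigest()[:16]


@dataclass
class ParcelMap:
    """One real value per parcel, aligned to an atlas order."""

    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ParcelMap values must be 1-D")

    def check_atlas(self, atlas: AtlasMetadata) -> None:
        if self.values.size != atlas.n_parcels:
            raise ValueError(
                f"map '{self.name}' has {self.values.size} values, "
                f"atlas has {atlas.n_parcels} parcels"
            )


@dataclass
class DisorderEffectSet:
    """Parcels x disorders matrix of Cohen's d case-control effect sizes."""

    effects: np.ndarray
    disorder_id: list[str]
    n_cases: np.ndarray | None = None
    n_controls: np.ndarray | None = None

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        self.disorder_id = list(self.disorder_id)
        if self.effects.ndim != 2 or self.effects.shape[1] != len(self.disorder_id):
            raise ValueError("effects must be parcels x disorders")
        for attr in ("n_cases", "n_controls"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if v.shape != (len(self.disorder_id),) or np.any(v <= 0):
                    raise ValueError(f"{attr} must be positive, one per disorder")
                setattr(self, attr, v)

    @property
    def n_disorders(self) -> int:
        return len(self.disorder_id)

    def column(self, disorder: str, units: str = "Cohen's d") -> ParcelMap:
        j = self.disorder_id.index(disorder)
        return ParcelMap(self.effects[:, j], name=disorder, units=units)

    def drop(self, disorder: str) -> "DisorderEffectSet":
        j = self.disorder_id.index(disorder)
        keep = [k for k in range(self.n_disorders) if k != j]
        return DisorderEffectSet(
            self.effects[:, keep],
            [self.disorder_id[k] for k in keep],
            None if self.n_cases is None else self.n_cases[keep],
            None if self.n_controls is None else self.n_controls[keep],
        )


MATRIX_KINDS = ("coalteration", "affinity", "connectivity", "similarity")
_SYMMETRY_TOL = 1e-10


@dataclass
class SquareMatrix:
    """Labelled n x n matrix over parcels (or disorders, for similarity matrices)."""

    entries: np.ndarray
    labels: list[str]
    kind: str = "connectivity"

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.entries.shape != (n, n):
            raise ValueError(f"entries must be {n}x{n} to match labels")
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"kind must be one of {MATRIX_KINDS}")
        finite = np.isfinite(self.entries)
        asym = np.nanmax(np.abs(np.where(finite & finite.T, self.entries - self.entries.T, 0.0)), initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix of kind {self.kind!r} asymmetric beyond {_SYMMETRY_TOL} (max dev {asym:.3g})")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class ConnectivityBundle:
    """Normative connectome: cortico-cortical matrix + subcortical seed profiles.

    ``cortical`` is the 68x68 (atlas-sized) matrix whose diagonal is treated as
    absent; ``subcortical_seeds`` holds one seed-to-cortex row per subcortical
    structure (14 for the standard aseg set).
    """

    cortical: SquareMatrix
    subcortical_seeds: np.ndarray
    subcortical_labels: list[str]
    modality: str = "rs-fMRI"

    def __post_init__(self):
        self.subcortical_seeds = np.asarray(self.subcortical_seeds, dtype=float)
        self.subcortical_labels = list(self.subcortical_labels)
        if self.modality not in ("rs-fMRI", "DTI"):
            raise ValueError("modality must be 'rs-fMRI' or 'DTI'")
        ns = len(self.subcortical_labels)
        if self.subcortical_seeds.shape != (ns, self.cortical.n):
            raise ValueError(
                f"subcortical_seeds must be {ns}x{self.cortical.n}"
            )
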