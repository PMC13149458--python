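"""Core domain types and delimited-text I/O for connectome cohorts.

A connectome is a square, symmetric, nonnegative weight matrix over the
regions of an atlas, interpreted as a weighted undirected graph.  Edge
weights carry one of five connectivity metrics: SIFT2-weighted streamline
count (SC) or the mean of a diffusion-tensor scalar along connecting
streamlines (FA, AD, RD, MD).  Each subject contributes one connectome per
metric and per tractogram-filtering state (unfiltered / filtered).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlasLabels, aal90

logger = logging.getLogger(__name__)

METRICS = ("SC", "FA", "AD", "RD", "MD")
FILTERINGS = ("unfiltered", "filtered")
GROUPS = ("HC", "PD")
SEXES = ("F", "M")


class ConnectomeValidationError(ValueError):
    pass


class DimensionError(ConnectomeValidationError):
    pass


def validate_weights(weights: np.ndarray, metric: str, *, atol: float = 1e-10) -> np.ndarray:
    """Validate and canonicalize a weight matrix.

    Enforces: square, finite, nonnegative, symmetric, zero diagonal
    (nonzero diagonals are zeroed with a warning), and FA bounded by 1.
    Returns a float64 copy.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionError(f"weight matrix must be square, got shape {w.shape}")
    bad = np.argwhere(~np.isfinite(w))
    if bad.size:
        i, j = bad[0]
        raise ConnectomeValidationError(f"non-finite weight at cell ({i}, {j})")
    if (w < 0).any():
        i, j = np.argwhere(w < 0)[0]
        raise ConnectomeValidationError(f"negative weight {w[i, j]} at cell ({i}, {j})")
    if not np.allclose(w, w.T, rtol=0.0, atol=atol):
        raise ConnectomeValidationError("weight matrix is not symmetric")
    w = (w + w.T) / 2.0  # exact symmetry after tolerance check
    if np.any(np.diag(w) != 0.0):
        logger.warning("nonzero diagonal zeroed (self-connections are dropped)")
        np.fill_diagonal(w, 0.0)
    if metric == "FA" and (w > 1.0 + atol).any():
        raise ConnectomeValidationError("FA weights must lie in [0, 1]")
    return w


@dataclass
class Connectome:
    """One subject's weighted undirected brain network."""

    subject_id: str
    metric: str
    filtering: str
    weights: np.ndarray
    labels: RegionAtlasLabels = field(default_factory=aal90)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConnectomeValidationError(f"unknown metric {self.metric!r}")
        if self.filtering not in FILTERINGS:
            raise ConnectomeValidationError(f"unknown filtering state {self.filtering!r}")
        self.weights = validate_weights(self.weights, self.metric)
        if self.weights.shape[0] != len(self.labels):
            raise DimensionError(
                f"matrix is {self.weights.shape[0]}x{self.weights.shape[1]} but the "
                f"atlas has {len(self.labels)} regions"
            )

    @property
    def n_regions(self) -> int:
        return len(self.labels)


def upper_triangle_vector(c: Connectome) -> np.ndarray:
    """Strictly-upper-triangle edge weights in row-major order.

    For 90 regions this is the 4005-long feature vector fed to the SVM
    classifiers.  The ordering is identical for every subject sharing an
    atlas, and the connectome is exactly reconstructible from it.
    """
    n = c.n_regions
    iu = np.triu_indices(n, k=1)
    return c.weights[iu].copy()


def connectome_from_vector(vec: np.ndarray, labels: RegionAtlasLabels,
                           subject_id: str, metric: str, filtering: str) -> Connectome:
    """Inverse of :func:`upper_triangle_vector`."""
    n = len(labels)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    if vec.shape != iu[0].shape:
        raise DimensionError(f"expected {iu[0].size} edge values, got {vec.size}")
    w[iu] = vec
    w += w.T
    return Connectome(subject_id, metric, filtering, w, labels)


def connection_profile(c: Connectome, node: int) -> np.ndarray:
    """A node's row of the weight matrix — the GNN input feature vector."""
    if not 0 <= node < c.n_regions:
        raise IndexError(f"node {node} out of range 0..{c.n_regions - 1}")
    return c.weights[node].copy()


# -- file I/O ----------------------------------------------------------------

_FILENAME_RE = re.compile(
    r"^(?P<subject>.+)_(?P<metric>SC|FA|AD|RD|MD)_(?P<filtering>unfiltered|filtered)$"
)


def connectome_filename(subject_id: str, metric: str, filtering: str) -> str:
    """Canonical on-disk name: ``<subject>_<metric>_<filtering>.csv``."""
    return f"{subject_id}_{metric}_{filtering}.csv"


def parse_connectome_filename(path) -> tuple[str, str, str]:
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        raise ValueError(
            f"cannot parse subject/metric/filtering from filename {stem!r}; "
            "expected <subject>_<metric>_<filtering>.csv"
        )
    return m.group("subject"), m.group("metric"), m.group("filtering")


def _load_matrix_text(path) -> np.ndarray:
    """Read a whitespace- or comma-delimited numeric matrix, optional header."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    tokens = first.replace(",", " ").split()

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
        except ValueError:
            return False
        return True

    skip = 0 if all(_is_number(t) for t in tokens) else 1
    return np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)


def read_connectome(path, labels: RegionAtlasLabels | None = None, *,
                    subject_id: str | None = None, metric: str | None = None,
                    filtering: str | None = None) -> Connectome:
    """Read a delimited-text connectome matrix.

    Accepts whitespace- or comma-delimited matrices with an optional header
    row of region names (MRtrix ``tck2connectome`` output and spreadsheet
    exports both parse).  Upper-triangular-only matrices — a common dialect
    for undirected graphs — are mirrored to full symmetric form.  Metadata
    missing from the arguments is parsed from the filename
    ``<subject>_<metric>_<filtering>.csv``.
    """
    if labels is None:
        labels = aal90()
    if subject_id is None or metric is None or filtering is None:
        s, m, f = parse_connectome_filename(path)
        subject_id = subject_id or s
        metric = metric or m
        filtering = filtering or f

    w = _load_matrix_text(path)
    n = len(labels)
    if w.shape != (n, n):
        raise DimensionError(
            f"{path}: expected a {n}x{n} matrix, got {w.shape[0]}x{w.shape[1]}"
        )
    lower = np.tril(w, k=-1)
    upper = np.triu(w, k=1)
    if not lower.any() and upper.any():
        # upper-triangular dialect: mirror into the lower triangle
        w = upper + upper.T + np.diag(np.diag(w))
    return Connectome(subject_id, metric, filtering, w, labels)


def write_connectome(c: Connectome, path) -> None:
    """Write comma-delimited with a header row of region names.

    Values are written with ``repr`` round-trip precision so that
    read-after-write reproduces the weights exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(c.labels.names) + "\n")
        for row in c.weights:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")


# -- cohort ------------------------------------------------------------------


@dataclass
class CohortManifest:
    """Per-subject design table: subject_id, group (PD/HC), sex, age."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "sex", "age"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("manifest subject_id values must be unique")
        bad_group = set(self.table["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    def group_ids(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "subject_id"])

    def group_mask(self, group: str) -> np.ndarray:
        return (self.table["group"] == group).to_numpy()

    def require_two_groups(self, min_per_group: int = 2) -> None:
        for g in GROUPS:
            n = int(self.group_mask(g).sum())
            if n < min_per_group:
                raise ValueError(f"group {g} has {n} subjects; need >= {min_per_group}")

    def __len__(self) -> int:
        return len(self.table)


def read_manifest(path) -> CohortManifest:
    return CohortManifest(pd.read_csv(path, dtype={"subject_id": str}))


def write_manifest(manifest: CohortManifest, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(path, index=False)


@dataclass
class Cohort:
    """A manifest plus the connectomes of its subjects, sharing one atlas."""

    manifest: CohortManifest
    connectomes: dict[tuple[str, str, str], Connectome]
    labels: RegionAtlasLabels

    def __post_init__(self) -> None:
        known = set(self.manifest.subject_ids)
        for (sid, metric, filtering), c in self.connectomes.items():
            if sid not in known:
                raise ValueError(f"connectome subject {sid!r} absent from manifest")
            if c.labels.names != self.labels.names:
                raise ValueError(f"connectome {sid}/{metric}/{filtering} uses a different atlas")

    def get(self, subject_id: str, metric: str, filtering: str) -> Connectome:
        return self.connectomes[(subject_id, metric, filtering)]

    def stack(self, metric: str, filtering: str) -> np.ndarray:
        """(n_subjects, n_regions, n_regions) array in manifest order."""
        return np.stack([
            self.connectomes[(sid, metric, filtering)].weights
            for sid in self.manifest.subject_ids
        ])

    def edge_matrix(self, metric: str, filtering: str) -> np.ndarray:
        """(n_subjects, n_edges) strictly-upper-triangle design matrix."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.stack(metric, filtering)[:, iu[0], iu[1]]

    def available_metrics(self) -> list[str]:
        return sorted({m for (_, m, _) in self.connectomes}, key=METRICS.index)


def read_cohort(connectome_dir, manifest_path, labels: RegionAtlasLabels | None = None) -> Cohort:
    """Load every ``<subject>_<metric>_<filtering>.csv`` under a directory."""
    if labels is None:
        labels = aal90()
    manifest = read_manifest(manifest_path)
    connectomes: dict[tuple[str, str, str], Connectome] = {}
    for path in sorted(Path(connectome_dir).glob("*.csv")):
        try:
            sid, metric, filt = parse_connectome_filename(path)
        except ValueError:
            continue  # e.g. the manifest itself
        connectomes[(sid, metric, filt)] = read_connectome(
            path, labels, subject_id=sid, metric=metric, filtering=filt)
    return Cohort(manifest, connectomes, labels)


def write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.manifest, out / "manifest.csv")
    for (sid, metric, filt), c in cohort.connectomes.items():
        write_connectome(c, out / connectome_filename(sid, metric, filt))
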