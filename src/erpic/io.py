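"""Plain-text persistence: cohort TSV matrices + JSON manifests.

A cohort on disk is a directory of one TSV matrix per (subject, condition)
— rows are channels with a label column, the header carries sample times in
ms — plus a ``manifest.json`` tying files to subjects, groups and the
montage.  The manifest is written last, so its presence marks a complete
write.  Decompositions, feature matrices, models and run reports are
persisted as TSV/CSV/JSON as well; all numeric text round-trips at 1e-12
relative tolerance (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CONDITIONS, ERPCohort, N_SAMPLES, Subject, times_ms
from .errors import InvalidInputError
from .features import FeatureMatrix
from .ica import ICADecomposition
from .montage import Montage, standard_1020
from .synthetic import GroundTruth

MANIFEST_NAME = "manifest.json"
FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


def _erp_path(directory: Path, subject_id: str, condition: str) -> Path:
    return directory / f"{subject_id}_{condition}.tsv"


def write_cohort(cohort: ERPCohort, directory: str | Path) -> Path:
    """Write a cohort as TSV matrices plus a JSON manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = "channel\t" + "\t".join(f"{t:g}" for t in times_ms(cohort.n_samples))
    records = []
    for subj in cohort.subjects:
        files = {}
        for cond in cohort.conditions:
            path = _erp_path(directory, subj.id, cond)
            mat = cohort.get(subj.id, cond)
            with open(path, "w") as fh:
                fh.write(header + "\n")
                for label, row in zip(cohort.montage.labels, mat):
                    fh.write(label + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
            files[cond] = path.name
        records.append({"id": subj.id, "group": subj.group, "files": files})
    manifest = {
        "format_version": FORMAT_VERSION,
        "montage": list(cohort.montage.labels),
        "sampling_rate": cohort.sampling_rate,
        "epoch_ms": [0.0, 1000.0],
        "conditions": list(cohort.conditions),
        "subjects": records,
        "provenance": "external",
    }
    manifest_path = directory / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def read_cohort(manifest_path: str | Path, montage: Montage | None = None) -> ERPCohort:
    """Load a cohort written by :func:`write_cohort`.

    The channel order is forced to the manifest's montage order; shape or
    parse problems raise errors naming the offending subject/condition.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise InvalidInputError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    labels = manifest["montage"]
    if montage is None:
        std = standard_1020()
        if list(std.labels) == labels:
            montage = std
        else:
            raise InvalidInputError(
                "manifest montage differs from the standard 10-20 montage; "
                "pass a Montage explicitly"
            )
    directory = manifest_path.parent
    conditions = tuple(manifest.get("conditions", CONDITIONS))
    subjects, mats = [], []
    for rec in manifest["subjects"]:
        subjects.append(Subject(rec["id"], rec["group"]))
        per_cond = []
        for cond in conditions:
            path = directory / rec["files"][cond]
            if not path.exists():
                raise InvalidInputError(f"referenced file missing: {path}")
            df = pd.read_csv(path, sep="\t", index_col=0)
            if list(df.index) != labels:
                raise InvalidInputError(
                    f"subject {rec['id']!r}, condition {cond!r}: channel rows "
                    f"do not match the manifest montage"
                )
            mat = df.to_numpy(dtype=float)
            if mat.shape[1] != N_SAMPLES:
                raise InvalidInputError(
                    f"subject {rec['id']!r}, condition {cond!r}: expected "
                    f"{N_SAMPLES} samples, got {mat.shape[1]}"
                )
            per_cond.append(mat)
        mats.append(per_cond)
    return ERPCohort(
        subjects, np.asarray(mats), montage,
        manifest.get("sampling_rate", 250.0), conditions,
    )


# ---------------------------------------------------------------------------
# Ground truth sidecar


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar with planted mixing matrix and informative sources.

    Source curves are omitted (they are reproducible from the seed); the
    mixing matrix and the informative index set suffice for oracle checks.
    """
    payload = {
        "mixing": truth.mixing.tolist(),
        "informative": list(truth.informative),
        "source_names": list(truth.source_names),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Decompositions


def write_decomposition(decomp: ICADecomposition, directory: str | Path) -> Path:
    """Persist topographies/filters as labelled TSV and metadata as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = list(decomp.montage.labels) if decomp.montage else [
        f"ch{i}" for i in range(decomp.topographies.shape[0])
    ]
    topo = pd.DataFrame(decomp.topographies, index=labels,
                        columns=list(decomp.ic_labels))
    topo.to_csv(directory / "topographies.tsv", sep="\t", float_format=_FLOAT_FMT)
    filt = pd.DataFrame(decomp.filters, index=list(decomp.ic_labels), columns=labels)
    filt.to_csv(directory / "filters.tsv", sep="\t", float_format=_FLOAT_FMT)
    for cond, acts in decomp.grand_activations.items():
        pd.DataFrame(
            acts, index=list(decomp.ic_labels),
            columns=[f"{t:g}" for t in times_ms(acts.shape[1])],
        ).to_csv(directory / f"grand_activations_{cond}.tsv", sep="\t",
                 float_format=_FLOAT_FMT)
    meta = {
        "set_id": decomp.set_id,
        "seed": decomp.seed,
        "n_ics": decomp.n_ics,
        "sites": decomp.sites.tolist(),
        "ic_labels": list(decomp.ic_labels),
        "exclusions": [list(e) for e in decomp.exclusions],
        "montage": labels,
    }
    meta_path = directory / "decomposition.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta_path


def read_decomposition(directory: str | Path) -> ICADecomposition:
    directory = Path(directory)
    with open(directory / "decomposition.json") as fh:
        meta = json.load(fh)
    topo = pd.read_csv(directory / "topographies.tsv", sep="\t", index_col=0)
    filt = pd.read_csv(directory / "filters.tsv", sep="\t", index_col=0)
    grand = {}
    for path in sorted(directory.glob("grand_activations_*.tsv")):
        cond = path.stem.replace("grand_activations_", "")
        grand[cond] = pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
    std = standard_1020()
    montage = std if list(std.labels) == meta["montage"] else None
    return ICADecomposition(
        topographies=topo.to_numpy(dtype=float),
        filters=filt.to_numpy(dtype=float),
        grand_activations=grand,
        sites=np.asarray(meta["sites"], dtype=int),
        set_id=meta["set_id"],
        montage=montage,
        ic_labels=tuple(meta["ic_labels"]),
        seed=meta["seed"],
        exclusions=tuple((e[0], int(e[1]), float(e[2])) for e in meta["exclusions"]),
    )


# ---------------------------------------------------------------------------
# Feature matrices


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV with subject index, group column and one column per FeatureSpec key."""
    out = fm.values.copy()
    out.insert(0, "group", fm.groups)
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    if "group" not in df.columns:
        raise InvalidInputError("feature CSV lacks the 'group' column")
    groups = df.pop("group")
    return FeatureMatrix(df, groups)
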