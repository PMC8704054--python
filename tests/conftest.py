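import numpy as np
import pytest

from qtycode.report import synth_sequence
from qtycode.qty_engine import apply_substitution
from qtycode.structure import HelixSpec, build_bundle


@pytest.fixture(scope="session")
def synth_pair():
    """Deterministic synthetic 7TM native/variant pair."""
    record, annotation = synth_sequence(seed=7)
    result = apply_substitution(record, annotation)
    return record, annotation, result


@pytest.fixture(scope="session")
def bundles(synth_pair):
    """Same-coordinate native and QTY-relabeled 7-helix bundles."""
    record, annotation, result = synth_pair
    spec = HelixSpec(n_residues=22)
    native = build_bundle(7, spec, 10.0, sequence=record, annotation=annotation,
                          model_id="native")
    import dataclasses
    variant = build_bundle(
        7, spec, 10.0, sequence=result.variant,
        annotation=dataclasses.replace(annotation, record_id=result.variant.id),
        model_id="variant",
    )
    return native, variant


def quaternion_superpose_rmsd(reference: np.ndarray, mobile: np.ndarray):
    """Independent superposition oracle (Horn's quaternion method).

    Builds the 4x4 key matrix from the correlation of centred coordinates;
    the eigenvector of the largest eigenvalue is the optimal rotation
    quaternion.  Returns (rotation matrix, rmsd).
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    rc = ref - ref.mean(axis=0)
    mc = mob - mob.mean(axis=0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(key)
    q = vecs[:, np.argmax(vals)]
    w, x, y, z = q
    rot = np.array([
        [w*w + x*x - y*y - z*z, 2*(x*y - w*z), 2*(x*z + w*y)],
        [2*(x*y + w*z), w*w - x*x + y*y - z*z, 2*(y*z - w*x)],
        [2*(x*z - w*y), 2*(y*z + w*x), w*w - x*x - y*y + z*z],
    ])
    moved = mc @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - rc) ** 2, axis=1))))
    return rot, rmsd
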