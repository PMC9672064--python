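"""Small shared helpers: hashing, logging, seeded RNG derivation."""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np

logger = logging.getLogger("voxelsurv")


def stable_hash(*objects) -> str:
    """SHA-256 digest of arrays / scalars / strings / dicts, order-sensitive.

    Used by leakage sentinels and determinism tests: two runs that produce
    byte-identical parameters produce identical digests.
    """
    h = hashlib.sha256()
    for obj in objects:
        _update(h, obj)
    return h.hexdigest()


def _update(h, obj) -> None:
    if obj is None:
        h.update(b"\x00none")
    elif isinstance(obj, np.ndarray):
        arr = np.ascontiguousarray(obj)
        h.update(str(arr.dtype).encode())
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    elif isinstance(obj, (str, bytes)):
        h.update(obj.encode() if isinstance(obj, str) else obj)
    elif isinstance(obj, (int, float, bool, np.integer, np.floating)):
        h.update(repr(obj).encode())
    elif isinstance(obj, dict):
        for k in sorted(obj, key=str):
            _update(h, str(k))
            _update(h, obj[k])
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            _update(h, item)
    else:  # dataclass-like or pandas
        try:
            import pandas as pd

            if isinstance(obj, pd.DataFrame):
                h.update(pd.util.hash_pandas_object(obj, index=True).values.tobytes())
                h.update(",".join(map(str, obj.columns)).encode())
                return
            if isinstance(obj, pd.Series):
                h.update(pd.util.hash_pandas_object(obj, index=True).values.tobytes())
                return
        except ImportError:  # pragma: no cover
            pass
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())


def derive_seed(seed: int, *salt) -> int:
    """Derive an independent child seed (< 2**31) from a parent seed and salt."""
    h = hashlib.sha256(repr((int(seed),) + salt).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def rng_from(seed: int, *salt) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *salt))


def as_bool_events(events) -> np.ndarray:
    e = np.asarray(events)
    if not np.isin(e, [0, 1, True, False]).all():
        raise ValueError("event indicator must be 0/1")
    return e.astype(bool)
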