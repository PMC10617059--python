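"""Seed derivation shared by all stages."""

import hashlib


def derive_seed(master: int, *tags) -> int:
    """Derive a stage-specific RNG seed from the master seed.

    Hashes ``(master, *tags)`` with blake2b so that every (stage, combination)
    pair gets an independent stream: adding or removing one pipeline
    combination never perturbs the seeds of another.  The result is always
    in ``[0, 2^31)`` and therefore valid for every scikit-learn/igraph seed.
    """
    h = hashlib.blake2b(digest_size=4)
    h.update(str(int(master)).encode())
    for tag in tags:
        h.update(b"/")
        h.update(str(tag).encode())
    return int.from_bytes(h.digest(), "big") % (2**31)
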