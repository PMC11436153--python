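"""Master-seed fan-out.

Stage seeds are derived by hashing ``(master_seed, stage_name)`` so that
adding a stage never perturbs the random stream of an existing one, and
every derived seed stays below 2**31.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, name: str) -> int:
    digest = hashlib.blake2s(f"{int(master)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
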