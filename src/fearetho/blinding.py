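"""Keyed, format-preserving codec for blinded trial identifiers.

Hand scoring must be blind to subject, group, and session, so each trial's
(rat, session, trial) identifiers are encrypted into an opaque token of the
form ``word + digits`` (e.g. ``abundant28515581``): a wordlist word chosen
by keyed hash, followed by a keyed permutation of the identifier digits and
a short authentication tag. Decoding with the correct key recovers the
identifiers exactly; a wrong key raises, never returns wrong identifiers.

The permutation is a 4-round Feistel network over the 8-digit identifier
space (a bijection on 0..10^8-1), keyed with HMAC-SHA256. Distinct
identifiers therefore always yield distinct tokens.
"""

from __future__ import annotations

import hashlib
import hmac
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .errors import AuthenticationError, ParseError

_HALF = 10_000  # each Feistel half is 4 decimal digits
_ROUNDS = 4
_TAG_DIGITS = 6
_TOKEN_RE = re.compile(r"^([a-z]+)(\d{14})$")

#: Valid identifier ranges (1-based, inclusive).
MAX_RAT = 9999
MAX_SESSION = 100
MAX_TRIAL = 100


@dataclass(frozen=True)
class BlindToken:
    """Opaque ``word + digits`` identifier handed to an observer."""

    word: str
    digits: str

    def __str__(self) -> str:
        return self.word + self.digits


@lru_cache(maxsize=1)
def load_wordlist() -> tuple[str, ...]:
    """Packaged wordlist: lowercase alphabetic words, one per line."""
    text = resources.files("fearetho.data").joinpath("wordlist.txt").read_text()
    words = tuple(w.strip() for w in text.splitlines() if w.strip())
    assert all(w.isalpha() and w.islower() for w in words)
    return words


def _prf(key: bytes, *parts: object) -> int:
    msg = ":".join(str(p) for p in parts).encode()
    return int.from_bytes(hmac.new(key, msg, hashlib.sha256).digest()[:8], "big")


def _feistel(key: bytes, idx: int, *, inverse: bool) -> int:
    left, right = divmod(idx, _HALF)
    rounds = range(_ROUNDS)
    if not inverse:
        for r in rounds:
            left, right = right, (left + _prf(key, "F", r, right)) % _HALF
    else:
        for r in reversed(rounds):
            left, right = (right - _prf(key, "F", r, left)) % _HALF, left
    return left * _HALF + right


def _key_bytes(key: str | bytes) -> bytes:
    if isinstance(key, str):
        key = key.encode()
    if not key:
        raise ParseError("blinding key must be non-empty")
    return key


def _pack(rat: int, session: int, trial: int) -> int:
    for name, value, hi in (
        ("rat", rat, MAX_RAT),
        ("session", session, MAX_SESSION),
        ("trial", trial, MAX_TRIAL),
    ):
        if not (isinstance(value, int) and 1 <= value <= hi):
            raise ParseError(f"{name} identifier {value!r} outside 1..{hi}")
    return (rat - 1) * _HALF + (session - 1) * MAX_TRIAL + (trial - 1)


def _unpack(idx: int) -> tuple[int, int, int]:
    rat, rem = divmod(idx, _HALF)
    session, trial = divmod(rem, MAX_TRIAL)
    return rat + 1, session + 1, trial + 1


def _tag(key: bytes, payload: str) -> str:
    return f"{_prf(key, 'tag', payload) % 10**_TAG_DIGITS:0{_TAG_DIGITS}d}"


def _word_for(key: bytes, payload: str) -> str:
    words = load_wordlist()
    return words[_prf(key, "word", payload) % len(words)]


def encode_trial(rat: int, session: int, trial: int, key: str | bytes) -> BlindToken:
    """Encrypt (rat, session, trial) into a blind ``word + digits`` token."""
    kb = _key_bytes(key)
    payload = f"{_feistel(kb, _pack(rat, session, trial), inverse=False):08d}"
    return BlindToken(word=_word_for(kb, payload), digits=payload + _tag(kb, payload))


def decode_trial(token: BlindToken | str, key: str | bytes) -> tuple[int, int, int]:
    """Recover (rat, session, trial) from a token; wrong key/tampering raises."""
    kb = _key_bytes(key)
    m = _TOKEN_RE.match(str(token))
    if not m:
        raise ParseError(f"malformed blind token {str(token)!r}")
    word, digits = m.groups()
    payload, tag = digits[:8], digits[8:]
    if tag != _tag(kb, payload) or word != _word_for(kb, payload):
        raise AuthenticationError("blind token failed verification under this key")
    rat, session, trial = _unpack(_feistel(kb, int(payload), inverse=True))
    # Range check guards against forged payloads that verify by chance.
    if session > MAX_SESSION or trial > MAX_TRIAL or rat > MAX_RAT:
        raise AuthenticationError("decoded identifiers out of range")
    return rat, session, trial
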