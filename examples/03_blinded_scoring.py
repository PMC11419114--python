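"""Blind trial identifiers for unbiased hand scoring.

Each (rat, session, trial) triple is encrypted into an opaque word+digits
token; scorers see only the token, and the key holder can decode it back.
"""

from fearetho import decode_trial, encode_trial

KEY = "lab-secret-2024"

print("trial identifiers -> blind tokens:")
for rat, session, trial in [(1, 1, 3), (1, 1, 4), (32, 2, 1)]:
    token = encode_trial(rat, session, trial, KEY)
    back = decode_trial(token, KEY)
    print(f"  rat {rat:>2}, session {session}, trial {trial} -> {token}  (decodes to {back})")

print("\nconsecutive trials share no digit structure, so observers cannot")
print("infer session or trial order; decoding with a wrong key raises an")
print("authentication error rather than returning wrong identifiers.")
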