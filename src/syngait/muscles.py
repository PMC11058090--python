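"""Canonical muscle set of the recording montage.

Thirteen ipsilateral lower-limb muscles, identified by two-letter codes.
The column order of every delimited-text EMG file and of every muscle-weight
vector follows ``MUSCLE_LABELS``.
"""

MUSCLE_LABELS: tuple[str, ...] = (
    "ME",  # gluteus medius
    "MA",  # gluteus maximus
    "FL",  # tensor fasciae latae
    "RF",  # rectus femoris
    "VM",  # vastus medialis
    "VL",  # vastus lateralis
    "ST",  # semitendinosus
    "BF",  # biceps femoris
    "TA",  # tibialis anterior
    "PL",  # peroneus longus
    "GM",  # gastrocnemius medialis
    "GL",  # gastrocnemius lateralis
    "SO",  # soleus
)

MUSCLE_NAMES: dict[str, str] = {
    "ME": "gluteus medius",
    "MA": "gluteus maximus",
    "FL": "tensor fasciae latae",
    "RF": "rectus femoris",
    "VM": "vastus medialis",
    "VL": "vastus lateralis",
    "ST": "semitendinosus",
    "BF": "biceps femoris",
    "TA": "tibialis anterior",
    "PL": "peroneus longus",
    "GM": "gastrocnemius medialis",
    "GL": "gastrocnemius lateralis",
    "SO": "soleus",
}

N_MUSCLES = len(MUSCLE_LABELS)
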