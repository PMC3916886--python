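"""External identity-key providers.

Standard InChIKey is deliberately not re-implemented; when RDKit's InChI
support is available it can be plugged into :func:`compute_keys` as the
``EXTERNAL_STANDARD`` level.  Provider keys are attached verbatim.
"""

from __future__ import annotations

from typing import Optional

from .records import MoleculeRecord
from .sdf_io import record_to_block


def rdkit_inchikey(record: MoleculeRecord) -> Optional[str]:
    """Standard InChIKey via RDKit; None when the record does not convert."""
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem.inchi import MolToInchiKey
    except ImportError:  # pragma: no cover - rdkit is a hard dependency
        return None
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromMolBlock(record_to_block(record), sanitize=True)
    if mol is None:
        return None
    key = MolToInchiKey(mol)
    return key or None
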