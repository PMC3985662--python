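"""Optional mzML import (and a minimal profile-mode export for round trips).

``import_mzml`` reduces centroided spectra to the envelope-table format by
extracting, for every peptide x charge in a pool, the peaks inside an m/z
window around the expected isotopic envelope.  Spectra are associated with
time labels by acquisition order via an explicit label list (the package
does no retention-time modeling).

The export writes one spectrum per time label containing all peptides'
sticks rendered as narrow Gaussian profiles — just enough mzML (indexless,
zlib/base64 binary arrays) for pyteomics to read back.
"""

from __future__ import annotations

import base64
import struct
import zlib

import numpy as np
from lxml import etree

from .spectra import DELTA_MASS_D, PROTON_MASS, IsotopicEnvelope, monoisotopic_mass, to_mz
from .synthetic import PeptidePool
from .envelopes import measurable_amides

__all__ = ["import_mzml", "export_mzml"]


def import_mzml(
    path: str,
    pool: PeptidePool,
    time_labels: list[object],
    mz_margin: float = 1.5,
    min_intensity: float = 0.0,
) -> tuple[list[IsotopicEnvelope], list[dict]]:
    """Extract per-peptide envelopes from centroided mzML spectra.

    Spectra are taken in file order and paired with ``time_labels``
    (seconds, or the sentinels).  For each peptide and charge the window is
    [mono m/z - margin/z, (mono + (n_amides + 3) Da + margin)/z].  Returns
    (envelopes, skip report); peptides with no matched peaks in a spectrum
    land in the skip report instead of raising.
    """
    spectra = _read_mzml_spectra(path)
    envelopes: list[IsotopicEnvelope] = []
    skipped: list[dict] = []
    if not spectra:
        return envelopes, [{"reason": "empty file"}]
    labels = time_labels[: len(spectra)]
    for (mzs, intens), label in zip(spectra, labels):
        for p in pool:
            mono = monoisotopic_mass(p.sequence)
            n = measurable_amides(p.sequence)
            for z in p.charge_states:
                lo = (mono - mz_margin) / z + PROTON_MASS
                hi = (mono + (n + 3) * DELTA_MASS_D + mz_margin) / z + PROTON_MASS
                sel = (mzs >= lo) & (mzs <= hi) & (intens > min_intensity)
                if not sel.any():
                    skipped.append(
                        {"peptide_id": p.peptide_id, "charge": z, "time_s": str(label)}
                    )
                    continue
                envelopes.append(
                    IsotopicEnvelope(
                        peptide_id=p.peptide_id,
                        chain=p.chain,
                        start=p.start,
                        end=p.end,
                        sequence=p.sequence,
                        charge=z,
                        time_s=label,
                        mz=np.asarray(mzs[sel], dtype=float),
                        intensity=np.asarray(intens[sel], dtype=float),
                    )
                )
    return envelopes, skipped


def _read_mzml_spectra(path: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Minimal mzML spectrum reader: 32/64-bit float binary arrays, zlib or
    uncompressed, identified by the standard m/z- and intensity-array CV
    accessions."""
    ns = "{http://psi.hupo.org/ms/mzml}"
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    tree = etree.parse(str(path))
    for spec in tree.iter(f"{ns}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            dtype = "<f4" if "MS:1000521" in accs else "<f8"
            binary = bda.find(f"{ns}binary")
            raw = base64.b64decode(binary.text or "")
            if "MS:1000574" in accs:
                raw = zlib.decompress(raw)
            arr = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accs:
                arrays["mz"] = arr
            elif "MS:1000515" in accs:
                arrays["intensity"] = arr
        if "mz" in arrays and "intensity" in arrays:
            spectra.append((arrays["mz"], arrays["intensity"]))
    return spectra


def _encode(arr: np.ndarray) -> str:
    raw = struct.pack(f"<{len(arr)}d", *arr)
    return base64.b64encode(zlib.compress(raw)).decode()


_CV = {
    "mz": ("MS:1000514", "m/z array"),
    "intensity": ("MS:1000515", "intensity array"),
}


def export_mzml(
    envelopes: list[IsotopicEnvelope],
    path: str,
    profile_sigma_mz: float = 0.01,
    grid_step: float = 0.005,
) -> list[object]:
    """Render stick envelopes as Gaussian profiles, one combined spectrum
    per time label, and write a minimal mzML file.  Returns the label order
    written (pass it back to :func:`import_mzml`)."""
    by_time: dict[str, list[IsotopicEnvelope]] = {}
    label_order: list[object] = []
    for env in envelopes:
        key = str(env.time_s)
        if key not in by_time:
            by_time[key] = []
            label_order.append(env.time_s)
        by_time[key].append(env)

    nsmap = {None: "http://psi.hupo.org/ms/mzml"}
    root = etree.Element("mzML", nsmap=nsmap, version="1.1.0")
    run = etree.SubElement(root, "run", id="hdxpipe_export")
    spec_list = etree.SubElement(
        run, "spectrumList", count=str(len(label_order)), defaultDataProcessingRef="dp"
    )
    for si, label in enumerate(label_order):
        envs = by_time[str(label)]
        lo = min(e.mz[0] for e in envs) - 1.0
        hi = max(e.mz[-1] for e in envs) + 1.0
        grid = np.arange(lo, hi, grid_step)
        profile = np.zeros_like(grid)
        for e in envs:
            for mz, inten in zip(e.mz, e.intensity):
                profile += inten * np.exp(-0.5 * ((grid - mz) / profile_sigma_mz) ** 2)
        keep = profile > profile.max() * 1e-6
        mz_arr, int_arr = grid[keep], profile[keep]

        spec = etree.SubElement(
            spec_list, "spectrum", index=str(si),
            id=f"scan={si + 1}", defaultArrayLength=str(len(mz_arr)),
        )
        etree.SubElement(
            spec, "cvParam", cvRef="MS", accession="MS:1000511",
            name="ms level", value="1",
        )
        bal = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for kind, arr in (("mz", mz_arr), ("intensity", int_arr)):
            data = _encode(arr)
            bda = etree.SubElement(bal, "binaryDataArray", encodedLength=str(len(data)))
            etree.SubElement(
                bda, "cvParam", cvRef="MS", accession="MS:1000523",
                name="64-bit float", value="",
            )
            etree.SubElement(
                bda, "cvParam", cvRef="MS", accession="MS:1000574",
                name="zlib compression", value="",
            )
            acc, nm = _CV[kind]
            etree.SubElement(
                bda, "cvParam", cvRef="MS", accession=acc, name=nm, value="",
            )
            etree.SubElement(bda, "binary").text = data
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )
    return label_order
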