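"""Shared fixtures: worked cluster examples and tiny on-disk spectra files."""

from __future__ import annotations

import base64
import struct

import numpy as np
import pytest

from ms2transfer.records import ClusterAssignment, PsmRecord

SRRM1 = "Serine/arginine repetitive matrix protein 1"


def make_isomer_cluster_psms() -> list[PsmRecord]:
    """The published five-spectrum phospho-isomer cluster (cluster id 75).

    Three spectra identified the same peptide with the phospho group on
    position 3 or 5; two spectra (rawfile1 scan 5602, rawfile3 scan 6033)
    are unidentified.
    """
    return [
        PsmRecord("rawfile1", 5582, "RASPSPRAA", "RApSPSPRAA", (SRRM1,), score=105.0),
        PsmRecord("rawfile1", 5588, "RASPSPRAA", "RASPpSPRAA", (SRRM1,), score=95.0),
        PsmRecord("rawfile1", 5602),
        PsmRecord("rawfile2", 6025, "RASPSPRAA", "RApSPSPRAA", (SRRM1,), score=88.0),
        PsmRecord("rawfile3", 6033),
    ]


@pytest.fixture
def isomer_cluster():
    psms = make_isomer_cluster_psms()
    assignment = ClusterAssignment("p10", {p.key: 75 for p in psms})
    return psms, assignment


# ---------------------------------------------------------------------------
# Minimal mzML emission (test fixture generator only; the package never
# writes mzML)
# ---------------------------------------------------------------------------


def _encode_array(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *[float(v) for v in values])
    return base64.b64encode(raw).decode("ascii")


def _binary_array(values, accession: str, name: str) -> str:
    encoded = _encode_array(values)
    return f"""<binaryDataArray encodedLength="{len(encoded)}">
<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>
<binary>{encoded}</binary>
</binaryDataArray>"""


def mzml_spectrum_xml(
    index: int,
    scan: int,
    ms_level: int,
    mz,
    intensity,
    precursor_mz: float = 0.0,
    charge: int | None = None,
) -> str:
    level_params = (
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>'
    )
    precursor = ""
    if ms_level == 2:
        charge_param = (
            f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{charge}"/>'
            if charge
            else ""
        )
        precursor = f"""<precursorList count="1"><precursor>
<selectedIonList count="1"><selectedIon>
<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor_mz}"/>
{charge_param}
</selectedIon></selectedIonList>
</precursor></precursorList>"""
    return f"""<spectrum index="{index}" id="controllerType=0 controllerNumber=1 scan={scan}" defaultArrayLength="{len(mz)}">
{level_params}
{precursor}
<binaryDataArrayList count="2">
{_binary_array(mz, "MS:1000514", "m/z array")}
{_binary_array(intensity, "MS:1000515", "intensity array")}
</binaryDataArrayList>
</spectrum>"""


def write_minimal_mzml(path: str, spectra: list[dict]) -> None:
    """Write a minimal standards-shaped mzML file for reader tests.

    ``spectra`` entries: dicts with scan, ms_level, mz, intensity, and for
    MS2 optionally precursor_mz and charge.
    """
    body = "\n".join(
        mzml_spectrum_xml(
            index=i,
            scan=s["scan"],
            ms_level=s.get("ms_level", 2),
            mz=s.get("mz", []),
            intensity=s.get("intensity", []),
            precursor_mz=s.get("precursor_mz", 0.0),
            charge=s.get("charge"),
        )
        for i, s in enumerate(spectra)
    )
    content = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<run id="run1">
<spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">
{body}
</spectrumList>
</run>
</mzML>"""
    with open(path, "w") as handle:
        handle.write(content)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
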