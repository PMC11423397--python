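import base64

import numpy as np
import pytest

from metalpept import AT1, AT2, PeptideSequence


@pytest.fixture
def at1() -> PeptideSequence:
    return AT1


@pytest.fixture
def at2() -> PeptideSequence:
    return AT2


def minimal_mzml(mz, intensity, ms_level=1, nce=None, selected_mz=None) -> str:
    """A small centroided mzML document built by hand for reader tests."""

    def b64(arr):
        return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()

    params = [f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>']
    prec = ""
    if ms_level == 2:
        sel = (
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{selected_mz:.4f}"/>'
        )
        act = (
            f'<cvParam cvRef="MS" accession="MS:1000045" name="collision energy" '
            f'value="{nce}"/>'
            if nce is not None
            else ""
        )
        prec = (
            "<precursorList count=\"1\"><precursor>"
            "<isolationWindow>"
            '<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="2.5"/>'
            '<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="2.5"/>'
            "</isolationWindow>"
            f"<selectedIonList count=\"1\"><selectedIon>{sel}</selectedIon></selectedIonList>"
            f"<activation>{act}</activation>"
            "</precursor></precursorList>"
        )
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="r1"><spectrumList count="1">
  <spectrum index="0" id="scan=1" defaultArrayLength="{len(mz)}">
   {''.join(params)}
   {prec}
   <binaryDataArrayList count="2">
    <binaryDataArray>
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
     <binary>{b64(mz)}</binary>
    </binaryDataArray>
    <binaryDataArray>
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
     <binary>{b64(intensity)}</binary>
    </binaryDataArray>
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run></mzML>"""
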