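# CAD "test result" indicator phrases
abnormal stress test
positive stress test
cardiac catheterization
coronary angiogram
abnormal ekg
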