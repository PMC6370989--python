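# Default 6 MV photon energy spectrum (flattened beam, central axis).
# Tabulated (energy MeV, relative fluence) lines; normalized on load.
# The shape is a generic flattening-filtered 6 MV bremsstrahlung
# spectrum (mode near 0.5-1.25 MeV, mean near 1.7 MeV); it is editable
# configuration because the true machine spectrum is implicit in the
# tuned electron beam of any given installation.
0.25 0.019
0.50 0.052
0.75 0.081
1.00 0.094
1.25 0.095
1.50 0.089
1.75 0.081
2.00 0.072
2.25 0.063
2.50 0.055
2.75 0.047
3.00 0.040
3.25 0.034
3.50 0.029
3.75 0.024
4.00 0.020
4.25 0.017
4.50 0.014
4.75 0.012
5.00 0.010
5.25 0.008
5.50 0.007
5.75 0.005
6.00 0.004
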