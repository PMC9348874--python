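# Default element properties: symbol, vdW radius (Angstrom), atomic weight (g/mol).
# Radii follow the consistent van der Waals radii derived from CSD contact
# statistics (Alvarez); weights follow the IUPAC standard atomic weights.
# The file is plain data and may be replaced by the user (-e/--elements).
H   1.20    1.008
He  1.43    4.003
Li  2.12    6.94
Be  1.98    9.012
B   1.91   10.81
C   1.77   12.011
N   1.66   14.007
O   1.50   15.999
F   1.46   18.998
Ne  1.58   20.180
Na  2.50   22.990
Mg  2.51   24.305
Al  2.25   26.982
Si  2.19   28.085
P   1.90   30.974
S   1.89   32.06
Cl  1.82   35.45
Ar  1.83   39.948
K   2.73   39.098
Ca  2.62   40.078
Ti  2.46   47.867
Cr  2.45   51.996
Mn  2.45   54.938
Fe  2.44   55.845
Co  2.40   58.933
Ni  2.40   58.693
Cu  2.38   63.546
Zn  2.39   65.38
Ga  2.32   69.723
Ge  2.29   72.630
As  1.88   74.922
Se  1.82   78.971
Br  1.86   79.904
Kr  2.25   83.798
Rb  3.21   85.468
Sr  2.84   87.62
Mo  2.45   95.95
Ru  2.46  101.07
Rh  2.44  102.906
Pd  2.15  106.42
Ag  2.53  107.868
Cd  2.49  112.414
Sn  2.42  118.710
Sb  2.47  121.760
Te  1.99  127.60
I   2.04  126.904
Xe  2.06  131.293
Cs  3.48  132.905
Ba  3.03  137.327
Pt  2.29  195.084
Au  2.32  196.967
Hg  2.45  200.592
Pb  2.60  207.2
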