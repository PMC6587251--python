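H SYNF010101
D Synthetic tie-free scale 1 (hand-written fixture, not a database entry)
R
A synthetic
T synthetic fixture catalog
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.62   -1.53    0.28   -0.90    1.29    0.71   -0.74    0.48   -0.40    1.38
    1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    1.08   -0.81    0.26
//
H SYNF020101
D Synthetic tie-free scale 2 (hand-written fixture, not a database entry)
R
A synthetic
T synthetic fixture catalog
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    8.10    10.5    11.6     13.    5.50    10.8    12.3    9.00    10.4    16.8
    16.9    11.3    16.3    19.8    8.00    9.20    8.60    17.0    23.6    18.0
//
H SYNF030101
D Synthetic tie-free scale 3 (hand-written fixture, not a database entry)
R
A synthetic
T synthetic fixture catalog
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.50    3.10    0.20    2.9      -1.     0.7     3.3     0.05    -0.6    -1.8
   -1.75    2.6     -1.3    -2.5     0.4     0.3     -0.4    -1.5    -3.4    -2.3
//
H SYNF040101
D Synthetic tie-free scale 4 (hand-written fixture, not a database entry)
R
A synthetic
T synthetic fixture catalog
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.00    2.00    3.00    4.00    5.00    6.00    7.00    8.00    9.00   10.00
   11.00   12.00   13.00   14.00   15.00   16.00   17.00   18.00   19.00   20.00
//
H SYNF050101
D Synthetic tie-free scale 5 (hand-written fixture, not a database entry)
R
A synthetic
T synthetic fixture catalog
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.046   0.291   0.134   0.105   0.128   0.180   0.151   0.000   0.230   0.186
   0.185   0.219   0.221   0.290   0.131   0.062   0.108   0.140   0.409   0.298
//
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
R PMID:7108955
A Kyte, J. and Doolittle, R.F.
T A simple method for displaying the hydropathic character of a protein
J J. Mol. Biol. 157, 105-132 (1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7     4.2    -0.9    -1.3
//
H SYNF060101
D Synthetic incomplete scale (hand-written fixture with a missing value)
R
A synthetic
T synthetic fixture catalog
J none
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.11    0.22    0.33    0.44    0.55    0.66    0.77    0.88    0.99    1.11
    1.22    1.33      NA    1.55    1.66    1.77    1.88    1.99    2.11    2.22
//
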