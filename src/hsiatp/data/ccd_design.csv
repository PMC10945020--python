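treatment,soy_lecithin,soy_oil,duration,lactic_acid,orange_extract,atp_measured
1,3.33,1.875,75,292.5,0.28,-7.54
2,3.33,1.875,75,337.5,0.28,-6.85
3,4.44,1.250,90,270.0,0.42,-4.84
4,3.33,1.875,75,247.5,0.28,-5.49
5,2.22,2.500,90,315.0,0.13,-4.62
6,3.33,1.875,75,292.5,0.28,-4.92
7,2.22,2.500,60,315.0,0.42,-8.66
8,1.11,1.875,75,292.5,0.27,-8.19
9,3.33,1.875,105,292.5,0.28,-8.04
10,3.33,1.875,45,292.5,0.28,-7.82
11,3.33,1.875,75,292.5,0.28,-4.85
12,2.22,1.250,90,315.0,0.41,-7.62
13,4.44,2.500,60,315.0,0.13,-4.85
14,4.44,2.500,60,270.0,0.43,-5.30
15,4.44,1.250,60,315.0,0.42,-4.99
16,2.22,1.250,90,270.0,0.13,-6.14
17,3.33,3.125,75,292.5,0.28,-8.17
18,4.44,1.250,90,315.0,0.13,-7.63
19,2.22,1.250,60,315.0,0.13,-4.90
20,4.44,2.500,90,315.0,0.43,-7.92
21,2.22,1.250,60,270.0,0.41,-7.68
22,4.44,1.250,60,270.0,0.13,-7.15
23,3.33,1.875,75,292.5,0.57,-7.95
24,5.55,1.875,75,292.5,0.28,-4.60
25,2.22,2.500,90,270.0,0.42,-7.95
26,3.33,1.875,75,292.5,0.28,-4.90
27,4.44,2.500,90,270.0,0.13,-7.94
28,3.33,1.875,75,292.5,0.28,-4.37
29,3.33,1.875,75,292.5,0.28,-5.15
30,2.22,2.500,60,270.0,0.13,-5.61
31,3.33,1.875,75,292.5,-0.01,-8.23
32,3.33,0.625,75,292.5,0.27,-8.14
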