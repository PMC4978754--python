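age,1975–1979,1980–1984,1985–1989,1990–1994,1995–1999,2000–2004,2005–2009,2010–2014
15–19,4.63,4.11,3.46,1.66,0.72,0.78,0.83,0.57
20–24,6.44,6.53,5.41,3.28,2.18,2.38,3.15,2.36
25–29,4.00,4.59,3.77,2.32,1.79,2.17,2.63,2.39
30–34,2.36,2.86,2.41,1.76,1.40,1.91,2.34,1.93
35–39,1.47,1.84,1.58,1.36,1.17,1.76,2.37,1.95
40–44,0.87,1.26,1.15,0.97,1.21,1.84,2.40,2.03
45–49,0.55,0.84,0.72,0.74,0.94,1.75,2.39,2.10
50–54,0.37,0.47,0.48,0.53,0.78,1.60,2.34,2.25
55–59,0.26,0.31,0.35,0.36,0.55,1.20,1.99,2.04
60–64,0.17,0.26,0.22,0.19,0.31,0.70,1.49,1.72
65–69,0.10,0.18,0.13,0.13,0.21,0.48,0.94,1.26
70–74,0.08,0.11,0.10,0.12,0.10,0.26,0.55,0.76
75–79,0.06,0.07,0.04,0.06,0.08,0.12,0.31,0.48
80–84,0.02,0.04,0.05,0.02,0.05,0.09,0.11,0.22
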