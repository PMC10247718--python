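year,imported_pct,domestic_pct
2004,36.0,64.0
2005,31.0,69.0
2006,24.5,75.5
2007,12.6,87.4
2008,4.6,95.4
2009,10.2,89.8
2010,8.3,91.7
2011,5.9,94.1
2012,7.4,92.6
2013,7.6,92.4
2014,6.3,93.7
2015,7.1,92.9
2016,5.3,94.7
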