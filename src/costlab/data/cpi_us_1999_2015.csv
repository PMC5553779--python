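# US CPI-U, all urban consumers, annual averages (index 1982-84 = 100).
# Reference series for rescaling historical hospital costs to 2015 dollars.
year,cpi
1999,166.6
2000,172.2
2001,177.1
2002,179.9
2003,184.0
2004,188.9
2005,195.3
2006,201.6
2007,207.342
2008,215.303
2009,214.537
2010,218.056
2011,224.939
2012,229.594
2013,232.957
2014,236.736
2015,237.017
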