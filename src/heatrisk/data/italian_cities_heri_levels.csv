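city,group,period,level_name,mean_lst,sd_lst,coverage_area_pct,total_pop_freq_pct,elderly_pop_freq_pct,total_pop_density,elderly_pop_density
Turin,inland,day,very low,12.5,0.5,0.4,0.0,0.0,4.6,0.8
Turin,inland,day,low,18.4,2.0,27.4,1.2,1.1,91.0,13.7
Turin,inland,day,moderate,22.6,1.2,55.0,15.8,14.5,622.2,94.3
Turin,inland,day,high,22.2,1.6,14.6,60.3,59.9,8915.3,1464.4
Turin,inland,day,very high,20.8,2.0,2.6,22.7,24.5,18598.5,3320.6
Milan,inland,day,very low,20.4,0.2,1.8,0.7,0.6,1580.9,231.1
Milan,inland,day,low,23.8,0.6,49.1,2.4,2.4,199.8,32.3
Milan,inland,day,moderate,24.3,0.4,39.3,58.8,56.8,6140.0,947.8
Milan,inland,day,high,24.6,0.2,8.4,31.3,32.8,15249.2,2564.2
Milan,inland,day,very high,24.8,0.1,1.4,6.8,7.4,19313.8,3333.8
Padua,inland,day,very low,20.8,1.6,0.5,0.1,0.1,110.2,18.3
Padua,inland,day,low,25.7,0.5,48.7,2.8,2.5,61.9,8.0
Padua,inland,day,moderate,26.5,0.6,33.2,8.0,7.1,251.4,33.2
Padua,inland,day,high,26.1,0.8,8.2,34.4,30.8,4376.9,581.4
Padua,inland,day,very high,26.3,0.3,9.4,54.7,59.5,6102.8,984.8
Bologna,inland,day,very low,20.2,0.8,1.2,0.1,0.1,50.2,9.4
Bologna,inland,day,low,25.7,1.7,55.0,4.2,3.8,66.6,12.4
Bologna,inland,day,moderate,28.6,0.7,37.0,24.1,22.6,564.2,106.9
Bologna,inland,day,high,28.1,0.7,6.5,66.4,68.1,8907.5,1851.0
Bologna,inland,day,very high,27.9,0.4,0.3,5.2,5.4,15634.3,3303.9
Florence,inland,day,very low,20.2,1.3,2.1,0.0,0.0,19.5,3.3
Florence,inland,day,low,24.7,1.2,44.3,2.1,2.0,52.3,9.8
Florence,inland,day,moderate,27.5,0.7,41.7,4.4,4.4,118.4,22.7
Florence,inland,day,high,28.2,0.6,8.7,56.4,55.6,7231.0,1368.4
Florence,inland,day,very high,28.6,0.3,3.2,37.1,38.0,12886.6,2535.5
Rome,inland,day,very low,13.2,2.4,0.2,0.0,0.0,30.4,3.6
Rome,inland,day,low,24.9,1.5,8.2,0.4,0.3,61.6,7.9
Rome,inland,day,moderate,30.4,1.2,76.9,6.6,6.0,109.3,14.7
Rome,inland,day,high,31.2,0.7,10.8,58.6,58.3,6889.3,1021.2
Rome,inland,day,very high,31.3,0.3,3.9,34.4,35.4,11237.0,1723.5
Genoa,coastal,day,very low,11.0,1.5,8.7,0.1,0.1,15.5,3.4
Genoa,coastal,day,low,15.5,1.9,81.4,5.3,5.4,81.8,17.4
Genoa,coastal,day,moderate,19.3,2.5,3.6,9.2,9.6,3344.5,719.3
Genoa,coastal,day,high,20.0,1.8,5.8,74.0,73.6,15976.2,3296.8
Genoa,coastal,day,very high,18.4,0.9,0.5,11.4,11.3,27449.1,5660.1
Naples,coastal,day,very low,12.8,2.6,0.7,0.0,0.0,67.6,7.9
Naples,coastal,day,low,22.7,1.9,8.0,0.2,0.2,108.3,11.5
Naples,coastal,day,moderate,27.9,1.5,56.0,8.5,7.1,867.3,77.5
Naples,coastal,day,high,28.6,1.8,20.0,39.3,31.9,11253.2,960.8
Naples,coastal,day,very high,28.9,0.9,15.3,52.0,60.8,19496.8,2399.2
Bari,coastal,day,very low,16.3,3.1,0.0,0.0,0.0,0.0,0.0
Bari,coastal,day,low,25.0,1.1,0.3,0.0,0.0,38.2,4.1
Bari,coastal,day,moderate,30.4,0.4,88.9,9.2,8.5,86.6,10.4
Bari,coastal,day,high,30.1,0.7,7.6,56.1,54.5,6175.5,778.0
Bari,coastal,day,very high,30.2,0.4,3.2,34.7,37.0,9075.2,1254.5
Palermo,coastal,day,very low,16.6,2.2,0.2,0.0,0.0,191.5,25.4
Palermo,coastal,day,low,25.6,1.1,20.8,0.6,0.6,64.8,7.9
Palermo,coastal,day,moderate,28.1,1.0,52.9,2.6,2.7,114.2,13.8
Palermo,coastal,day,high,27.8,0.7,17.8,52.3,52.1,6824.6,809.5
Palermo,coastal,day,very high,28.0,0.4,8.3,44.5,44.6,12403.0,1478.9
Catania,coastal,day,very low,12.3,3.9,0.4,0.0,0.0,7.9,2.8
Catania,coastal,day,low,26.2,3.3,4.7,0.4,0.5,92.8,14.1
Catania,coastal,day,moderate,32.2,1.4,84.1,19.1,16.3,257.7,28.2
Catania,coastal,day,high,31.5,2.2,7.2,42.8,41.1,6705.9,822.2
Catania,coastal,day,very high,32.0,0.6,3.6,37.7,42.1,11722.8,1672.8
Turin,inland,night,very low,6.4,0.5,15.5,0.3,0.3,45.6,6.3
Turin,inland,night,low,8.4,0.8,62.2,9.5,8.1,327.6,46.3
Turin,inland,night,moderate,9.5,1.1,11.9,34.1,33.0,6229.5,996.2
Turin,inland,night,high,10.8,0.7,7.8,34.0,34.8,9455.0,1602.3
Turin,inland,night,very high,11.4,0.8,2.6,22.1,23.8,18700.2,3327.7
Milan,inland,night,very low,8.1,0.2,0.5,0.0,0.0,47.0,6.4
Milan,inland,night,low,10.5,0.6,45.8,2.4,2.0,216.7,29.0
Milan,inland,night,moderate,11.0,0.5,44.7,60.6,58.7,5550.2,859.2
Milan,inland,night,high,11.0,0.6,7.7,30.7,32.5,16256.0,2761.7
Milan,inland,night,very high,11.7,0.1,1.3,6.3,6.8,19333.2,3336.6
Padua,inland,night,very low,8.8,0.2,5.5,0.3,0.3,55.7,7.1
Padua,inland,night,low,10.3,0.5,63.6,4.2,3.6,68.4,8.8
Padua,inland,night,moderate,11.0,0.5,15.0,12.4,10.8,860.0,111.4
Padua,inland,night,high,10.7,0.5,7.5,34.4,30.9,4807.9,639.9
Padua,inland,night,very high,11.2,0.3,8.4,48.7,54.4,6061.9,1003.4
Bologna,inland,night,very low,15.7,0.3,83.1,7.9,6.9,82.5,14.5
Bologna,inland,night,low,17.1,0.6,9.5,16.5,16.0,1506.1,294.9
Bologna,inland,night,moderate,17.3,0.5,6.0,57.5,58.5,8241.7,1703.8
Bologna,inland,night,high,18.1,0.4,0.9,9.6,9.9,9256.0,1918.4
Bologna,inland,night,very high,18.6,0.5,0.5,8.5,8.7,15633.9,3240.1
Florence,inland,night,very low,14.5,0.2,17.3,0.5,0.4,30.6,5.5
Florence,inland,night,low,15.5,0.6,68.2,5.0,4.9,82.0,15.3
Florence,inland,night,moderate,16.6,0.9,6.4,23.8,23.7,4096.0,783.0
Florence,inland,night,high,17.1,0.4,5.7,41.5,40.8,8075.4,1522.5
Florence,inland,night,very high,17.6,0.4,2.4,29.2,30.2,13704.5,2725.7
Rome,inland,night,very low,7.1,1.3,0.2,0.0,0.0,24.2,2.9
Rome,inland,night,low,15.0,0.5,26.0,1.1,1.0,55.7,7.5
Rome,inland,night,moderate,16.0,0.6,59.4,6.8,6.1,145.7,19.4
Rome,inland,night,high,16.8,0.6,10.6,58.2,57.9,6983.6,1037.0
Rome,inland,night,very high,17.5,0.6,3.8,33.9,35.0,11256.6,1728.5
Genoa,coastal,night,very low,1.9,1.9,0.1,0.0,0.0,58.6,13.8
Genoa,coastal,night,low,10.6,0.6,60.2,1.6,1.6,34.1,7.0
Genoa,coastal,night,moderate,12.0,0.6,32.7,8.4,8.7,323.6,69.4
Genoa,coastal,night,high,12.4,1.2,6.4,77.4,77.1,15269.7,3156.8
Genoa,coastal,night,very high,11.7,1.0,0.6,12.6,12.6,26094.7,5416.5
Naples,coastal,night,very low,7.0,1.6,0.3,0.0,0.0,550.0,55.7
Naples,coastal,night,low,12.2,1.3,2.8,0.1,0.1,142.4,18.0
Naples,coastal,night,moderate,14.9,0.7,60.3,7.1,6.0,676.7,60.1
Naples,coastal,night,high,15.4,0.9,20.9,39.8,32.1,10910.5,927.0
Naples,coastal,night,very high,15.6,0.5,15.7,53.0,61.8,19397.8,2383.3
Bari,coastal,night,very low,12.7,0.4,10.8,1.1,1.0,85.3,10.0
Bari,coastal,night,low,13.8,0.4,79.1,11.4,10.4,120.3,14.3
Bari,coastal,night,moderate,14.6,0.6,6.2,45.4,44.7,6077.8,775.7
Bari,coastal,night,high,15.1,0.5,3.8,40.5,42.5,8844.9,1201.2
Bari,coastal,night,very high,15.2,0.3,0.1,1.6,1.4,13200.0,1547.3
Palermo,coastal,night,very low,11.5,0.6,0.1,0.0,0.0,0.0,0.0
Palermo,coastal,night,low,14.4,0.5,65.2,1.2,1.3,43.2,5.5
Palermo,coastal,night,moderate,16.0,1.0,10.5,7.5,8.1,1654.7,212.5
Palermo,coastal,night,high,16.5,0.7,15.8,46.3,45.9,6815.6,803.2
Palermo,coastal,night,very high,17.1,0.6,8.4,45.0,44.7,12341.2,1460.6
Catania,coastal,night,very low,3.2,1.1,0.2,0.0,0.0,0.0,0.0
Catania,coastal,night,low,10.6,1.8,4.0,0.1,0.1,18.8,3.2
Catania,coastal,night,moderate,15.0,0.8,83.5,13.6,11.6,184.5,20.2
Catania,coastal,night,high,15.2,0.7,8.0,43.3,40.2,6130.4,726.4
Catania,coastal,night,very high,15.6,0.8,4.3,43.0,48.1,11221.4,1604.6
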