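source,subject_id,body_mass_kg,rco2_ic_L_per_day,schoeller1988_L_per_day,schoeller1988_pct,racette1994_L_per_day,racette1994_pct,eq1_L_per_day,eq1_pct,speakman1997_L_per_day,speakman1997_pct,speakman1993_L_per_day,speakman1993_pct,coward1985_L_per_day,coward1985_pct
Schoeller and Webb,M17,67.5,566.7,579.3,2.2,571.4,0.8,567.5,0.1,,,548.9,-3.2,,
Schoeller and Webb,F25,72.0,439.0,448.9,2.2,440.4,0.3,436.2,-0.6,,,417.9,-4.8,,
Schoeller and Webb,F27,57.1,436.8,382.1,-12.5,374.2,-14.3,370.3,-15.2,,,353.6,-19.0,,
Schoeller and Webb,M28,67.5,611.5,608.2,-0.5,596.6,-2.4,590.9,-3.4,,,565.8,-7.5,,
Schoeller and Webb,M58,88.2,486.1,521.8,7.4,514.3,5.8,510.5,5.0,,,493.0,1.4,,
Westerterp et al.,1,73.2,508.0,495.0,-2.6,487.1,-4.1,483.2,-4.9,,,465.4,-8.4,,
Westerterp et al.,2,77.9,479.0,506.5,5.7,498.2,4.0,494.2,3.2,,,475.8,-0.7,,
Westerterp et al.,3,57.6,356.0,352.0,-1.1,346.5,-2.7,343.8,-3.4,,,331.4,-6.9,,
Westerterp et al.,4,72.0,457.0,441.4,-3.4,435.5,-4.7,432.6,-5.3,,,418.6,-8.4,,
Westerterp et al.,5,58.1,437.0,422.9,-3.2,414.3,-5.2,410.1,-6.2,,,391.8,-10.3,,
Westerterp et al.,6A,75.6,894.0,919.0,2.8,907.5,1.5,901.9,0.9,,,874.1,-2.2,,
Westerterp et al.,7A,64.7,818.0,931.9,13.9,920.6,12.5,915.1,11.9,,,887.7,8.5,,
Westerterp et al.,8A,71.0,981.0,947.5,-3.4,934.2,-4.8,927.7,-5.4,,,896.6,-8.6,,
Westerterp et al.,9A,77.9,1104.0,1085.9,-1.6,1070.4,-3.0,1062.8,-3.7,,,1026.8,-7.0,,
Seale et al.,1,100.4,531.0,550.7,3.7,538.0,1.3,531.7,0.1,,,505.3,-4.8,,
Seale et al.,2,50.3,392.0,407.4,3.9,398.5,1.7,394.2,0.6,,,375.5,-4.2,,
Seale et al.,3,59.0,331.0,343.2,3.7,336.3,1.6,333.0,0.6,,,318.4,-3.8,,
Seale et al.,4,52.6,451.0,442.1,-2.0,427.3,-5.3,420.1,-6.9,,,391.1,-13.3,,
Seale et al.,5,82.7,530.0,545.9,3.0,535.0,0.9,529.7,-0.1,,,506.4,-4.5,,
Seale et al.,6,86.2,550.0,545.2,-0.9,530.4,-3.6,523.1,-4.9,,,493.1,-10.3,,
Seale et al.,7,87.4,515.0,531.0,3.1,522.2,1.4,517.9,0.6,,,498.2,-3.3,,
Seale et al.,8,47.8,403.0,395.8,-1.8,383.8,-4.8,378.0,-6.2,,,354.2,-12.1,,
Seale et al.,9,79.9,494.0,511.1,3.5,503.2,1.9,499.3,1.1,,,481.3,-2.6,,
Schoeller et al.,ID,75.3,559.0,570.6,2.1,564.5,1.0,561.1,0.4,,,543.4,-2.8,,
Schoeller et al.,NM,75.6,614.0,598.5,-2.5,591.0,-3.7,587.3,-4.4,,,568.5,-7.4,,
Schoeller et al.,ED,76.3,633.0,591.5,-6.6,582.8,-7.9,578.4,-8.6,,,557.9,-11.9,,
Schoeller et al.,MK,69.5,541.0,543.6,0.5,531.5,-1.8,526.5,-2.7,537.2,-0.7,506.1,-6.5,529.3,-2.2
Schoeller et al.,JD,64.1,504.0,440.0,-12.7,432.7,-14.1,428.8,-14.9,438.3,-13.0,410.7,-18.5,340.5,-32.4
Schoeller et al.,DM,73.3,566.0,650.1,14.9,640.7,13.2,636.9,12.5,659.6,16.5,619.8,9.5,581.6,2.8
Schoeller et al.,AB,56.7,468.0,460.2,-1.7,452.6,-3.3,449.5,-4.0,463.3,-1.0,435.4,-7.0,443.6,-5.2
Schoeller et al.,LC,85.2,626.0,656.6,4.9,643.1,2.7,637.9,1.9,654.6,4.6,616.8,-1.5,632.3,1.0
Schoeller et al.,DP,63.1,529.0,519.6,-1.8,512.0,-3.2,508.7,-3.8,525.5,-0.7,493.4,-6.7,515.4,-2.6
Ravussin et al.,1,124.6,499.0,462.1,-7.4,452.6,-9.3,448.6,-10.1,415.0,-16.8,432.0,-13.4,398.7,-20.1
Ravussin et al.,2,61.4,356.0,413.3,16.1,404.7,13.7,401.2,12.7,370.9,4.2,386.2,8.5,318.8,-10.5
Ravussin et al.,3,137.6,535.0,556.6,4.0,543.2,1.5,537.5,0.5,483.4,-9.7,514.2,-3.9,443.9,-17.0
Ravussin et al.,4,80.9,393.0,503.8,28.2,489.9,24.7,483.9,23.1,422.8,7.6,459.9,17.0,321.3,-18.2
Ravussin et al.,5,101.8,370.0,402.3,8.7,393.6,6.4,389.9,5.4,357.8,-3.3,374.8,1.3,318.5,-13.9
Ravussin et al.,6,139.9,424.0,427.7,0.9,420.1,-0.9,416.9,-1.7,393.7,-7.1,403.4,-4.9,384.7,-9.3
Ravussin et al.,7,190.9,711.0,733.7,3.2,718.0,1.0,711.4,0.0,653.8,-8.0,683.9,-3.8,541.5,-23.8
Ravussin et al.,8,95.8,480.0,590.9,23.1,575.0,19.8,568.0,18.3,498.8,3.9,540.4,12.6,396.9,-17.3
Ravussin et al.,9,151.5,672.0,683.3,1.7,662.0,-1.5,652.5,-2.9,551.9,-17.9,615.6,-8.4,510.6,-24.0
Ravussin et al.,10,68.6,373.0,406.3,8.9,390.4,4.7,383.1,2.7,300.2,-19.5,355.6,-4.7,277.5,-25.6
Ravussin et al.,11,69.4,332.0,354.2,6.7,344.4,3.7,340.0,2.4,296.4,-10.7,323.0,-2.7,234.7,-29.3
Ravussin et al.,12,80.1,403.0,468.0,16.1,457.6,13.5,453.2,12.5,413.8,2.7,435.1,8.0,361.5,-10.3
Melanson et al.,1,63.0,310.6,299.4,-3.6,291.7,-6.1,286.6,-7.7,280.0,-9.8,263.8,-15.1,285.1,-8.2
Melanson et al.,2,82.8,457.4,447.0,-2.3,440.4,-3.7,436.6,-4.6,445.0,-2.7,418.1,-8.6,420.4,-8.1
Melanson et al.,3,74.8,455.8,476.2,4.5,467.5,2.6,463.5,1.7,474.2,4.0,445.5,-2.3,429.6,-5.7
Melanson et al.,4,61.0,346.8,361.6,4.3,354.6,2.2,351.0,1.2,356.6,2.8,335.2,-3.4,324.2,-6.5
Melanson et al.,5,93.8,471.3,465.4,-1.2,454.0,-3.7,449.0,-4.7,456.0,-3.2,428.7,-9.0,389.9,-17.3
Melanson et al.,6,48.9,293.4,325.6,11.0,318.5,8.6,314.6,7.2,316.0,7.7,297.2,1.3,291.0,-0.8
Melanson et al.,7,53.3,349.9,352.7,0.8,343.6,-1.8,339.1,-3.1,340.1,-2.8,320.0,-8.5,298.1,-14.8
Melanson et al.,8,91.5,444.2,447.8,0.8,437.8,-1.4,433.7,-2.4,444.1,0.0,417.3,-6.1,385.0,-13.3
Melanson et al.,9,71.6,442.8,429.6,-3.0,418.0,-5.6,412.6,-6.8,415.5,-6.2,390.9,-11.7,351.9,-20.5
Melanson et al.,10,111.6,514.4,550.8,7.1,539.5,4.9,533.7,3.7,540.7,5.1,508.3,-1.2,489.8,-4.8
Melanson et al.,11,95.0,437.1,540.4,23.6,526.7,20.5,519.7,18.9,520.7,19.1,489.9,12.1,461.6,5.6
Melanson et al.,12,115.0,423.1,470.5,11.2,461.6,9.1,457.5,8.1,468.0,10.6,439.7,3.9,421.2,-0.5
Melanson et al.,13,101.4,433.7,433.1,-0.1,423.7,-2.3,419.3,-3.3,426.5,-1.7,400.9,-7.6,376.7,-13.2
Melanson et al.,14,73.9,473.4,443.0,-6.4,428.9,-9.4,422.8,-10.7,424.5,-10.3,399.5,-15.6,335.1,-29.2
Melanson et al.,15,72.0,394.0,353.6,-10.3,344.8,-12.5,340.8,-13.5,344.8,-12.5,324.2,-17.7,296.4,-24.8
Melanson et al.,16,61.7,353.8,345.7,-2.3,335.6,-5.2,331.0,-6.5,332.3,-6.1,312.6,-11.6,274.7,-22.4
Melanson et al.,17,69.6,387.9,402.2,3.7,393.9,1.5,389.9,0.5,396.5,2.2,372.6,-3.9,354.4,-8.6
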